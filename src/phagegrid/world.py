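"""The torus lattice world: state arrays, EPS placement, initial seeding.

Each patch can hold at most one live cell (uninfected or infected), an
immutable EPS flag, a transient debris marker (remnant of a lysed cell)
and any number of free phage. Debris may co-occur with a live cell, since
a lysed cell's patch can be recolonized while the debris persists. All
neighborhood lookups wrap on both axes (torus), so there are no boundary
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import SimParams

__all__ = ["EMPTY", "UNINFECTED", "INFECTED", "GridState", "new_grid",
           "place_eps", "init_population", "grid_to_frame", "grid_from_frame"]

EMPTY, UNINFECTED, INFECTED = 0, 1, 2
_OCCUPANT_NAMES = {EMPTY: "empty", UNINFECTED: "uninfected", INFECTED: "infected"}
_OCCUPANT_CODES = {v: k for k, v in _OCCUPANT_NAMES.items()}


@dataclass
class GridState:
    """Mutable state of one lattice run.

    Arrays are indexed ``[row, col]`` (height x width). ``occupant`` holds
    the codes EMPTY/UNINFECTED/INFECTED; ``infected_age`` is steps since
    infection (meaningful only where occupant == INFECTED); ``debris``
    counts remaining steps of a dead-cell phage sink (0 = none); ``phage``
    is the free phage count per patch.
    """

    occupant: np.ndarray      # int8 (h, w)
    infected_age: np.ndarray  # int32 (h, w)
    eps: np.ndarray           # bool (h, w)
    debris: np.ndarray        # int32 (h, w)
    phage: np.ndarray         # int64 (h, w)
    step: int
    rng: np.random.Generator

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupant.shape

    @property
    def n_patches(self) -> int:
        return self.occupant.size

    # -- global tallies ----------------------------------------------------

    def n_uninfected(self) -> int:
        return int(np.count_nonzero(self.occupant == UNINFECTED))

    def n_infected(self) -> int:
        return int(np.count_nonzero(self.occupant == INFECTED))

    def n_debris(self) -> int:
        return int(np.count_nonzero(self.debris > 0))

    def total_phage(self) -> int:
        return int(self.phage.sum())

    def copy(self) -> "GridState":
        bg = type(self.rng.bit_generator)()
        bg.state = self.rng.bit_generator.state
        return GridState(
            occupant=self.occupant.copy(),
            infected_age=self.infected_age.copy(),
            eps=self.eps.copy(),
            debris=self.debris.copy(),
            phage=self.phage.copy(),
            step=self.step,
            rng=np.random.Generator(bg),
        )


def new_grid(params: SimParams, rng: np.random.Generator | None = None) -> GridState:
    """Create an empty world (no EPS, no cells, no phage) with its RNG."""
    h, w = params.height, params.width
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return GridState(
        occupant=np.zeros((h, w), dtype=np.int8),
        infected_age=np.zeros((h, w), dtype=np.int32),
        eps=np.zeros((h, w), dtype=bool),
        debris=np.zeros((h, w), dtype=np.int32),
        phage=np.zeros((h, w), dtype=np.int64),
        step=0,
        rng=rng,
    )


def place_eps(grid: GridState, params: SimParams) -> GridState:
    """Assign EPS to exactly ``round(E * n_patches)`` patches, in place.

    Random layout: an exact-count uniform sample without replacement, so
    the realized EPS fraction equals E for every seed. Clustered layout:
    whole rows are filled from row 0 upward until the allotment is reached
    (final partial row filled left to right), producing a single contiguous
    band; on a torus the band's position is immaterial. EPS never changes
    for the rest of the run.
    """
    if grid.eps.any():
        raise ValueError("EPS already placed on this grid")
    h, w = grid.shape
    n = grid.n_patches
    count = int(round(params.eps_fraction_E * n))
    if count == 0:
        return grid
    if params.eps_layout == "clustered_rows":
        flat = np.zeros(n, dtype=bool)
        flat[:count] = True
        grid.eps[:] = flat.reshape(h, w)
    else:
        idx = grid.rng.choice(n, size=count, replace=False)
        grid.eps.ravel()[idx] = True
    return grid


def init_population(grid: GridState, params: SimParams) -> GridState:
    """Seed initial cells and phage, in place.

    ``init_cell_frac`` of patches (exact count, sampled without
    replacement) each receive one uninfected cell; independently,
    ``init_phage_frac`` of patches each receive one burst's worth
    (``burst_b``) of free phage. The two samples are independent, so a
    patch may start with both a cell and phage.
    """
    n = grid.n_patches
    n_cells = int(round(params.init_cell_frac * n))
    n_phage_patches = int(round(params.init_phage_frac * n))
    if n_cells:
        idx = grid.rng.choice(n, size=n_cells, replace=False)
        grid.occupant.ravel()[idx] = UNINFECTED
    if n_phage_patches:
        idx = grid.rng.choice(n, size=n_phage_patches, replace=False)
        grid.phage.ravel()[idx] = params.burst_b
    return grid


# -- per-patch CSV snapshots ----------------------------------------------


def grid_to_frame(grid: GridState) -> pd.DataFrame:
    """Per-patch snapshot with 0-based row-major (x=col, y=row) coordinates."""
    h, w = grid.shape
    yy, xx = np.divmod(np.arange(h * w), w)
    return pd.DataFrame(
        {
            "x": xx,
            "y": yy,
            "eps": grid.eps.ravel().astype(int),
            "occupant": [_OCCUPANT_NAMES[c] for c in grid.occupant.ravel()],
            "infected_age": grid.infected_age.ravel(),
            "debris_remaining": grid.debris.ravel(),
            "phage": grid.phage.ravel(),
        }
    )


def grid_from_frame(df: pd.DataFrame, rng: np.random.Generator | None = None,
                    step: int = 0) -> GridState:
    """Rebuild a GridState from a snapshot written by :func:`grid_to_frame`."""
    w = int(df["x"].max()) + 1
    h = int(df["y"].max()) + 1
    order = np.lexsort((df["x"].to_numpy(), df["y"].to_numpy()))
    d = df.iloc[order]
    g = GridState(
        occupant=np.array([_OCCUPANT_CODES[o] for o in d["occupant"]],
                          dtype=np.int8).reshape(h, w),
        infected_age=d["infected_age"].to_numpy(np.int32).reshape(h, w),
        eps=d["eps"].to_numpy(bool).reshape(h, w),
        debris=d["debris_remaining"].to_numpy(np.int32).reshape(h, w),
        phage=d["phage"].to_numpy(np.int64).reshape(h, w),
        step=step,
        rng=rng if rng is not None else np.random.default_rng(0),
    )
    return g
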