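"""Mass-action counterpart of the spatial grid model.

Identical parameters, entities and finite population, but spatial
structure is abolished by global random relocation: after lysis (and
before new infections) the entire free-phage population is reassigned to
uniformly random patches, and after cell reproduction all live cells are
reassigned to distinct random patches. Localized phage diffusion is
turned off. With shuffling, interaction rates depend only on global
densities, so the run behaves as a finite-population, stochastic version
of mass action.

Clustered EPS layouts are rejected: once positions are shuffled every
step, only the total amount of EPS matters, so a clustered run would be
indistinguishable from a random one.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .metrics import StepStats, stats_to_frame, summarize_window
from .params import SimParams
from .spatial import _OutcomeTable, _collect_stats, _extinct, infection_phase, lysis_phase, reproduction_phase
from .world import EMPTY, GridState, init_population, new_grid, place_eps

__all__ = ["shuffle_phage", "shuffle_cells", "run_mass_action_grid"]


def shuffle_phage(grid: GridState, rng: Optional[np.random.Generator] = None) -> None:
    """Reassign every free phage to an independently uniform patch.

    Implemented as one multinomial draw of the total count over patches;
    the total is conserved exactly.
    """
    if rng is None:
        rng = grid.rng
    total = grid.total_phage()
    n = grid.n_patches
    counts = rng.multinomial(total, np.full(n, 1.0 / n))
    grid.phage[:] = counts.reshape(grid.shape)


def shuffle_cells(grid: GridState, rng: Optional[np.random.Generator] = None) -> None:
    """Relocate all live cells to a fresh uniform sample of distinct patches.

    Infected ages travel with their cells; the count of each occupant kind
    and the multiset of ages are preserved exactly, and no patch ends up
    with two cells.
    """
    if rng is None:
        rng = grid.rng
    live = grid.occupant != EMPTY
    states = grid.occupant[live]
    ages = grid.infected_age[live]
    k = states.size
    if k == 0:
        return
    dest = rng.choice(grid.n_patches, size=k, replace=False)
    grid.occupant[:] = EMPTY
    grid.infected_age[:] = 0
    grid.occupant.ravel()[dest] = states
    grid.infected_age.ravel()[dest] = ages


def run_mass_action_grid(params: SimParams, return_series: bool = False,
                         grid: Optional[GridState] = None):
    """Run the shuffled-grid mass-action model.

    Per step: lysis -> phage shuffle -> reproduction -> cell shuffle ->
    infection (no diffusion). Summaries match :func:`run_spatial`'s, with
    ``mode="mass_action"``.
    """
    if params.eps_layout != "random":
        raise ValueError(
            "mass-action runs require eps_layout='random': with global "
            "shuffling only the amount of EPS matters")
    if grid is None:
        grid = new_grid(params)
        place_eps(grid, params)
        init_population(grid, params)
    table = _OutcomeTable(params)
    series: list[StepStats] = []
    extinct_kind = None
    for _ in range(params.n_steps):
        bursts = lysis_phase(grid, params)
        shuffle_phage(grid)
        reproduction_phase(grid, params)
        shuffle_cells(grid)
        tallies = infection_phase(grid, params, table)
        grid.step += 1
        series.append(_collect_stats(grid, params, bursts, tallies))
        extinct_kind = _extinct(grid)
        if extinct_kind is not None:
            break
    summary = summarize_window(
        series, params, mode="mass_action",
        extinct=extinct_kind is not None,
        extinction_step=grid.step if extinct_kind is not None else None,
    )
    if return_series:
        return summary, stats_to_frame(series)
    return summary
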