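"""Spatial dynamics: one time step = lysis -> reproduction -> infection -> diffusion.

Each phase executes globally (across all patches) before the next begins.

Lysis: infected cells reaching their lifespan burst, releasing ``burst_b``
free phage into their patch and (optionally) leaving short-lived debris.

Reproduction: each uninfected cell independently attempts reproduction;
the daughter goes to a uniformly chosen empty orthogonal neighbor, falling
back to an empty diagonal neighbor, and fails if all eight neighbors hold
live cells. Cells never move once placed.

Infection: within a patch, free phage are processed one at a time. A phage
runs one Bernoulli trial per entity type present (uninfected cell k_C,
infected cell k_I, debris k_D, EPS k_E) in uniformly random order,
stopping at the first success; adsorption to anything but an uninfected
cell kills the phage. A cell infected mid-phase is immediately seen as an
infected cell by the remaining phage in the patch. The per-patch outcome
is sampled exactly (geometric waiting time to the first productive
infection, multinomial allocation of the rest) rather than phage by
phage, which is equivalent and much faster.

Diffusion: deterministic redistribution of each patch's phage over the
3x3 torus neighborhood by the kernel weights, with the resulting real
loads converted to integers by unbiased stochastic rounding.
"""

from __future__ import annotations

from itertools import permutations
from typing import Optional

import numpy as np

from .kernel import DiffusionKernel
from .metrics import RunSummary, StepStats, stats_to_frame, summarize_window
from .params import SimParams
from .world import EMPTY, INFECTED, UNINFECTED, GridState, init_population, new_grid, place_eps

__all__ = ["lysis_phase", "reproduction_phase", "infection_phase",
           "diffusion_phase", "step", "run_spatial", "first_success_probs"]

_ORTH = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, -1), (-1, 1), (1, -1), (1, 1))


# ---------------------------------------------------------------------------
# lysis


def lysis_phase(grid: GridState, params: SimParams) -> int:
    """Age infected cells, burst those at end of life; return burst count.

    Ages increment first, so a cell infected at step t bursts during the
    lysis phase of step t + infected_lifespan — exactly ``lifespan`` steps
    from infection to lysis. Pre-existing debris counters decrement first
    (expiring at 0), so a burst onto a debris patch refreshes the debris
    clock to the full lifespan.
    """
    infected = grid.occupant == INFECTED
    np.subtract(grid.debris, 1, out=grid.debris, where=grid.debris > 0)
    grid.infected_age[infected] += 1
    ripe = infected & (grid.infected_age >= params.infected_lifespan)
    n_bursts = int(np.count_nonzero(ripe))
    if n_bursts:
        grid.phage[ripe] += params.burst_b
        grid.occupant[ripe] = EMPTY
        grid.infected_age[ripe] = 0
        if params.debris_enabled:
            grid.debris[ripe] = params.debris_lifespan
    return n_bursts


# ---------------------------------------------------------------------------
# reproduction


def reproduction_phase(grid: GridState, params: SimParams) -> int:
    """Let uninfected cells reproduce into empty neighbors; return births.

    Reproductive fates (the Bernoulli draws) are decided for the pre-phase
    set of uninfected cells; placements are then applied sequentially in
    random cell order against the *current* occupancy, so two daughters
    never land on the same patch.
    """
    if params.cell_repro_prob == 0.0:
        return 0
    h, w = grid.shape
    rows, cols = np.nonzero(grid.occupant == UNINFECTED)
    n = rows.size
    if n == 0:
        return 0
    reproduces = grid.rng.random(n) < params.cell_repro_prob
    idx = np.nonzero(reproduces)[0]
    if idx.size == 0:
        return 0
    order = grid.rng.permutation(idx.size)
    occ = grid.occupant
    births = 0
    for j in idx[order]:
        r, c = int(rows[j]), int(cols[j])
        slots = [((r + dr) % h, (c + dc) % w) for dr, dc in _ORTH
                 if occ[(r + dr) % h, (c + dc) % w] == EMPTY]
        if not slots:
            slots = [((r + dr) % h, (c + dc) % w) for dr, dc in _DIAG
                     if occ[(r + dr) % h, (c + dc) % w] == EMPTY]
        if not slots:
            continue
        rr, cc = slots[int(grid.rng.integers(len(slots)))]
        occ[rr, cc] = UNINFECTED
        births += 1
    return births


# ---------------------------------------------------------------------------
# infection

# sink indices in probability vectors: 0=C (uninfected), 1=I, 2=D, 3=E, 4=escape
_SINKS = 4


def first_success_probs(ks: tuple[float, float, float, float]) -> np.ndarray:
    """Outcome distribution for one phage facing the given present sinks.

    ``ks`` holds the adsorption probabilities of the entity types present
    in the patch (0 for absent types), in the fixed order (C, I, D, E).
    The phage tries each *present* type once, in uniformly random order,
    stopping at the first success. Returns [p_C, p_I, p_D, p_E, p_escape],
    averaged over the random orderings. The escape probability is
    prod(1 - k) independent of order.
    """
    present = [i for i, k in enumerate(ks) if k > 0]
    p = np.zeros(_SINKS + 1)
    if not present:
        p[_SINKS] = 1.0
        return p
    perms = list(permutations(present))
    for perm in perms:
        surv = 1.0
        for i in perm:
            p[i] += surv * ks[i]
            surv *= 1.0 - ks[i]
    p[:_SINKS] /= len(perms)
    p[_SINKS] = float(np.prod([1.0 - ks[i] for i in present]))
    return p


class _OutcomeTable:
    """Cache of first-success outcome distributions keyed by sink bitmask."""

    def __init__(self, params: SimParams):
        self.ks = (params.k_C, params.k_I, params.k_D, params.k_E)
        self._cache: dict[int, np.ndarray] = {}

    def probs(self, has_c: bool, has_i: bool, has_d: bool, has_e: bool) -> np.ndarray:
        mask = has_c | (has_i << 1) | (has_d << 2) | (has_e << 3)
        p = self._cache.get(mask)
        if p is None:
            ks = (self.ks[0] if has_c else 0.0, self.ks[1] if has_i else 0.0,
                  self.ks[2] if has_d else 0.0, self.ks[3] if has_e else 0.0)
            p = first_success_probs(ks)
            self._cache[mask] = p
        return p


def _allocate(n: int, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multinomial split of n phage over (I, D, E, escape), C excluded."""
    q = probs[[1, 2, 3, _SINKS]].astype(float)
    s = q.sum()
    if s <= 0:  # no sinks at all: everyone escapes
        out = np.zeros(4, dtype=np.int64)
        out[3] = n
        return out
    return rng.multinomial(n, q / s)


def infection_phase(grid: GridState, params: SimParams,
                    table: Optional[_OutcomeTable] = None) -> dict:
    """Adsorb free phage to patch entities; return loss/infection tallies.

    Tallies: ``loss_C`` (productive infections), ``loss_I``, ``loss_D``,
    ``loss_E`` and ``infections_eps`` (new infections on EPS patches).
    """
    if table is None:
        table = _OutcomeTable(params)
    tallies = dict(loss_C=0, loss_I=0, loss_D=0, loss_E=0, infections_eps=0)
    active = np.nonzero(
        (grid.phage > 0)
        & ((grid.occupant != EMPTY) | grid.eps | (grid.debris > 0))
    )
    occ = grid.occupant
    rng = grid.rng
    for r, c in zip(*active):
        n = int(grid.phage[r, c])
        has_e = bool(grid.eps[r, c])
        has_d = bool(grid.debris[r, c] > 0)
        state = occ[r, c]
        if state == UNINFECTED and params.k_C > 0:
            p = table.probs(True, False, has_d, has_e)
            p_c = p[0]
            # failures before the first productive infection
            g = int(rng.geometric(p_c)) - 1 if p_c < 1.0 else 0
            if g >= n:
                # nobody infects the cell; condition the n outcomes on not-C
                cond = p.copy()
                cond[0] = 0.0
                counts = _allocate(n, cond, rng)
            else:
                pre = _allocate(g, np.where(np.arange(5) == 0, 0.0, p), rng)
                occ[r, c] = INFECTED
                grid.infected_age[r, c] = 0
                tallies["loss_C"] += 1
                if has_e:
                    tallies["infections_eps"] += 1
                post = table.probs(False, True, has_d, has_e)
                counts = pre + _allocate(n - g - 1, post, rng)
                grid.phage[r, c] = counts[3]  # escapes
                tallies["loss_I"] += int(counts[0])
                tallies["loss_D"] += int(counts[1])
                tallies["loss_E"] += int(counts[2])
                continue
        else:
            has_i = state == INFECTED
            p = table.probs(False, has_i, has_d, has_e)
            counts = _allocate(n, p, rng)
        grid.phage[r, c] = counts[3]
        tallies["loss_I"] += int(counts[0])
        tallies["loss_D"] += int(counts[1])
        tallies["loss_E"] += int(counts[2])
    return tallies


# ---------------------------------------------------------------------------
# diffusion


def diffusion_phase(grid: GridState, kernel: Optional[DiffusionKernel],
                    rng: Optional[np.random.Generator] = None) -> None:
    """Redistribute phage over the 3x3 torus neighborhood, in place.

    Loads are computed synchronously from the pre-phase counts; each
    patch's real-valued load is converted to an integer by flooring and
    adding one with probability equal to the fractional part (unbiased
    stochastic rounding).
    """
    if kernel is None:  # immobile phage (leave fraction 0)
        return
    if rng is None:
        rng = grid.rng
    src = grid.phage.astype(np.float64)
    load = np.zeros_like(src)
    wmat = kernel.as_array()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            load += wmat[dr + 1, dc + 1] * np.roll(src, (dr, dc), axis=(0, 1))
    base = np.floor(load)
    frac = load - base
    grid.phage[:] = base.astype(np.int64) + (rng.random(load.shape) < frac)


# ---------------------------------------------------------------------------
# step / run


def _collect_stats(grid: GridState, params: SimParams, bursts: int,
                   tallies: dict) -> StepStats:
    n = grid.n_patches
    n_un = grid.n_uninfected()
    n_inf = grid.n_infected()
    on_eps = grid.eps
    return StepStats(
        step=grid.step,
        C=n_un / n,
        I=n_inf / n,
        D=grid.n_debris() / n,
        E=float(on_eps.sum()) / n,
        P=grid.total_phage(),
        loss_C=tallies["loss_C"],
        loss_I=tallies["loss_I"],
        loss_D=tallies["loss_D"],
        loss_E=tallies["loss_E"],
        bursts=bursts,
        infections_eps=tallies["infections_eps"],
        n_uninfected=n_un,
        n_infected=n_inf,
        cells_on_eps=int(np.count_nonzero((grid.occupant == UNINFECTED) & on_eps)),
        phage_on_eps=int(grid.phage[on_eps].sum()),
    )


def step(grid: GridState, params: SimParams,
         kernel: Optional[DiffusionKernel] = None,
         table: Optional[_OutcomeTable] = None) -> StepStats:
    """Advance the world one step and return its end-of-step tallies."""
    if kernel is None and (params.sigma is not None or params.diffuse_fraction):
        kernel = params.kernel()
    bursts = lysis_phase(grid, params)
    reproduction_phase(grid, params)
    tallies = infection_phase(grid, params, table)
    diffusion_phase(grid, kernel)
    grid.step += 1
    return _collect_stats(grid, params, bursts, tallies)


def _extinct(grid: GridState) -> Optional[str]:
    live = grid.n_uninfected() + grid.n_infected()
    if live == 0:
        return "cells"
    if grid.total_phage() == 0 and grid.n_infected() == 0:
        return "phage"
    return None


def run_spatial(params: SimParams, return_series: bool = False,
                grid: Optional[GridState] = None):
    """Run the spatial model for ``params.n_steps`` steps.

    Initializes the world (EPS placement then population seeding) unless a
    pre-built ``grid`` is supplied. Stops early if cells go extinct, or if
    phage go extinct (no free phage and no latent infections); extinction
    is a reported outcome, not an error. Returns a
    :class:`~phagegrid.metrics.RunSummary`, or ``(summary, DataFrame)``
    of the per-step series when ``return_series`` is set.
    """
    if grid is None:
        grid = new_grid(params)
        place_eps(grid, params)
        init_population(grid, params)
    kernel = params.kernel()
    table = _OutcomeTable(params)
    series: list[StepStats] = []
    extinct_kind = None
    for _ in range(params.n_steps):
        series.append(step(grid, params, kernel, table))
        extinct_kind = _extinct(grid)
        if extinct_kind is not None:
            break
    summary = summarize_window(
        series, params, mode="spatial",
        extinct=extinct_kind is not None,
        extinction_step=grid.step if extinct_kind is not None else None,
    )
    if return_series:
        return summary, stats_to_frame(series)
    return summary
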