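"""Replication management, parameter sweeps, fixtures and table output.

Ensembles replicate a parameter set across random seeds and a small set
of initial (cell, phage) occupancy fractions, excluding extinct trials
from the averages and reporting the extinction count separately — the
convention used throughout the output tables.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .massaction import run_mass_action_grid
from .metrics import RunSummary, summarize_ensemble
from .ode import OdeParams, a_ode, c_bar, integrate_dde
from .params import SimParams
from .spatial import run_spatial
from .world import GridState, UNINFECTED, init_population, new_grid, place_eps

__all__ = ["DEFAULT_INITIAL_CONDITIONS", "child_seeds", "run_ensemble",
           "sweep", "make_fixture", "ode_table", "TABLE5_PRESET"]

#: Default trio of initial (cell fraction, phage fraction) occupancies.
DEFAULT_INITIAL_CONDITIONS: tuple[tuple[float, float], ...] = (
    (0.3, 0.3), (0.1, 0.1), (0.5, 0.5))

#: The published delay-ODE parameter sets (burst, delta, kappa, L, r), K=1e9.
TABLE5_PRESET: tuple[tuple[int, float, float, float, float], ...] = (
    (10, 0.1, 1e-10, 20, 0.03),
    (10, 0.1, 5e-11, 20, 0.03),
    (10, 0.05, 1e-10, 20, 0.03),
    (10, 0.3, 1e-10, 20, 0.03),
    (10, 0.1, 1e-10, 25, 0.03),
    (20, 0.3, 3e-11, 20, 0.03),
    (20, 0.4, 7e-11, 20, 0.03),
    (20, 0.2, 1e-10, 20, 0.03),
    (60, 0.3, 5e-11, 25, 0.04),
    (60, 0.4, 5e-11, 20, 0.03),
    (60, 0.045, 3e-11, 21, 0.03),
)


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent, platform-stable child seeds.

    Uses numpy's SeedSequence spawning, keeping each child seed below
    2**31 so it can be fed back anywhere a small integer seed is wanted.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_ensemble(params: SimParams, n_trials: int = 15,
                 initial_conditions: Sequence[tuple[float, float]] = DEFAULT_INITIAL_CONDITIONS,
                 mode: str = "spatial",
                 master_seed: Optional[int] = None) -> dict:
    """Run ``n_trials`` replicate trials and aggregate them into one row.

    Trials cycle through ``initial_conditions`` (so 15 trials over 3
    initial conditions means 5 seeds each), each with its own child seed
    derived from ``master_seed`` (default: ``params.seed``). ``mode``
    selects the spatial or the shuffled mass-action model.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    runner: Callable = {"spatial": run_spatial,
                        "mass_action": run_mass_action_grid}[mode]
    seeds = child_seeds(params.seed if master_seed is None else master_seed,
                        n_trials)
    runs: list[RunSummary] = []
    for i, seed in enumerate(seeds):
        cf, pf = initial_conditions[i % len(initial_conditions)]
        p = params.with_updates(seed=seed, init_cell_frac=cf, init_phage_frac=pf)
        runs.append(runner(p))
    row = summarize_ensemble(runs)
    row["mode"] = mode
    row["burst"] = params.burst_b
    row["EPS"] = params.eps_fraction_E
    return row


def sweep(params: SimParams, bursts: Sequence[int],
          eps_fractions: Sequence[float], n_trials: int = 15,
          mode: str = "spatial",
          initial_conditions: Sequence[tuple[float, float]] = DEFAULT_INITIAL_CONDITIONS,
          master_seed: Optional[int] = None) -> pd.DataFrame:
    """Ensemble rows for every burst x EPS combination, as a DataFrame."""
    rows = []
    seeds = child_seeds(params.seed if master_seed is None else master_seed,
                        len(bursts) * len(eps_fractions))
    i = 0
    for b in bursts:
        for e in eps_fractions:
            p = params.with_updates(burst_b=b, eps_fraction_E=e)
            rows.append(run_ensemble(p, n_trials=n_trials, mode=mode,
                                     initial_conditions=initial_conditions,
                                     master_seed=seeds[i]))
            i += 1
    df = pd.DataFrame(rows)
    order = ["burst", "EPS", "A_g", "A_ub_g", "alpha_b", "P_to_C", "P_to_I",
             "P_to_E", "P_to_D", "C_on_E", "P_on_E", "I_on_E",
             "n_extinct", "n_runs"]
    cols = [c for c in order if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    return df[cols]


def ode_table(preset: Sequence[tuple[int, float, float, float, float]] = TABLE5_PRESET,
              K: float = 1e9, C0: float = 1e6, P0: float = 1e4) -> pd.DataFrame:
    """Integrate each preset parameter row and tabulate A_ode results."""
    rows = []
    for b, delta, kappa, L, r in preset:
        p = OdeParams(r=r, K=K, kappa=kappa, delta=delta, b=b, L=L)
        traj = integrate_dde(p, C0=C0, P0=P0)
        row = {"burst": b, "delta": delta, "kappa": kappa, "L": L, "r": r,
               "A_ub_ode": K / c_bar(p), "status": traj.status}
        if traj.completed:
            res = a_ode(traj, p)
            row["A_ode"] = res["A_ode"]
            row["A_ode_windows"] = res["windows"]
        else:
            row["A_ode"] = np.nan
            row["A_ode_windows"] = None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures

FIXTURES = ("one_patch", "cross", "band", "stationary")


def make_fixture(name: str) -> tuple[SimParams, GridState]:
    """Deterministic tiny worlds used in tests and walkthroughs.

    - ``one_patch``: 1x1 world, one cell and one burst of phage on the
      single patch, no movement; every interaction is forced.
    - ``cross``: 3x3 world, one cell in the center, one phage in a corner.
    - ``band``: 10x10 world with a 3-row clustered EPS band, standard
      seeding.
    - ``stationary``: the band world advanced 500 steps from a fixed seed,
      a pre-equilibrated snapshot for stationarity-dependent checks.
    """
    if name == "one_patch":
        params = SimParams(width=1, height=1, burst_b=5, eps_fraction_E=0.0,
                           k_C=1.0, cell_repro_prob=0.0, diffuse_fraction=0.0,
                           n_steps=50, avg_window=10,
                           init_cell_frac=0.0, init_phage_frac=0.0, seed=1)
        grid = new_grid(params)
        grid.occupant[0, 0] = UNINFECTED
        grid.phage[0, 0] = 1
        return params, grid
    if name == "cross":
        params = SimParams(width=3, height=3, burst_b=5, eps_fraction_E=0.0,
                           k_C=1.0, cell_repro_prob=0.0, diffuse_fraction=0.5,
                           n_steps=100, avg_window=10,
                           init_cell_frac=0.0, init_phage_frac=0.0, seed=1)
        grid = new_grid(params)
        grid.occupant[1, 1] = UNINFECTED
        grid.phage[0, 0] = 1
        return params, grid
    if name in ("band", "stationary"):
        params = SimParams(width=10, height=10, burst_b=6, eps_fraction_E=0.3,
                           eps_layout="clustered_rows", k_C=0.25, k_E=0.35,
                           cell_repro_prob=0.1, diffuse_fraction=0.3,
                           n_steps=2000, avg_window=500, seed=7)
        grid = new_grid(params)
        place_eps(grid, params)
        init_population(grid, params)
        if name == "stationary":
            from .spatial import step as _step
            kernel = params.kernel()
            for _ in range(500):
                _step(grid, params, kernel)
        return params, grid
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
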