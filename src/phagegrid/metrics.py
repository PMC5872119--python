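"""Equilibrium-referenced amplification metrics and run summaries.

At a well-mixed (mass-action) reproductive equilibrium each successful
phage infection leads, on average, to exactly one new successful
infection: alpha * b = 1, where b is the burst size and alpha is the
fraction of all free-phage loss routes that are productive infections,

    alpha = k_C C / (k_C C + k_I I + k_D D + k_E E),

with C, I, D, E the global patch-fraction densities of uninfected cells,
infected cells, debris and EPS. Evaluating alpha * b from a spatially
structured run therefore measures how far spatial self-organization lifts
the system above the mass-action equilibrium.

When superinfection and debris binding are off (k_I = k_D = 0) the cell
density solving alpha*b = 1 is closed form, C_hat = k_E E / (k_C (b-1)),
and the amplification attributable to spatial structure is
A_g = C_obs / C_hat, bounded by A_ub,g = 1 / C_hat (a grid entirely full
of cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import SimParams

__all__ = [
    "StepStats", "RunSummary", "alpha", "c_hat", "amplification_Ag",
    "alpha_b_from_Ag", "summarize_window", "summarize_ensemble",
    "stats_to_frame",
]


@dataclass
class StepStats:
    """Global tallies recorded at the end of one time step.

    Densities are patch fractions; ``P`` is a raw phage count. Losses are
    numbers of phage adsorbed this step, by sink: ``loss_C`` productive
    infections, ``loss_I`` superinfections, ``loss_D`` debris, ``loss_E``
    EPS. ``infections_eps`` counts this step's new infections that occurred
    on EPS-bearing patches. ``cells_on_eps`` / ``phage_on_eps`` are the
    numbers of uninfected cells and free phage sitting on EPS patches.
    """

    step: int
    C: float
    I: float
    D: float
    E: float
    P: int
    loss_C: int = 0
    loss_I: int = 0
    loss_D: int = 0
    loss_E: int = 0
    bursts: int = 0
    infections_eps: int = 0
    n_uninfected: int = 0
    n_infected: int = 0
    cells_on_eps: int = 0
    phage_on_eps: int = 0


def stats_to_frame(series: Sequence[StepStats]) -> pd.DataFrame:
    """Stack per-step tallies into a DataFrame (one row per step)."""
    cols = [f.name for f in fields(StepStats)]
    return pd.DataFrame({c: [getattr(s, c) for s in series] for c in cols})


@dataclass
class RunSummary:
    """Window-averaged outputs of one run, mirroring the table columns."""

    mode: str                      # "spatial" | "mass_action"
    alpha_b: float                 # mean per-step alpha*b over the window
    A_g: Optional[float]           # None when debris/superinfection active
    A_ub_g: Optional[float]
    mean_C: float
    mean_I: float
    mean_D: float
    mean_P: float
    C_on_E: float                  # fraction of uninfected cells on EPS
    P_on_E: float                  # fraction of free phage on EPS
    I_on_E: float                  # fraction of infections on EPS
    loss_per_burst: dict           # {"P_to_C": .., "P_to_I": .., "P_to_E": .., "P_to_D": ..}
    extinct: bool
    extinction_step: Optional[int]
    alpha_b_q10: float             # 10th percentile of per-step alpha*b
    alpha_b_q90: float
    n_steps_run: int
    window: int


def alpha(C: float, I: float, D: float, E: float,
          k_C: float, k_I: float, k_D: float, k_E: float) -> float:
    """Fraction of free-phage loss routes that are productive infections."""
    den = k_C * C + k_I * I + k_D * D + k_E * E
    if den <= 0:
        raise ValueError("alpha undefined: no phage loss routes (denominator 0)")
    return k_C * C / den


def c_hat(params: SimParams, I: Optional[float] = None,
          D: Optional[float] = None) -> float:
    """Mass-action equilibrium cell density (patch fraction).

    With k_I = k_D = 0 this is the closed form k_E E / (k_C (b-1)). When
    superinfection or debris binding is active, callers must supply I and
    D; the result is then only approximate, because those densities need
    not take their mass-action-equilibrium values in a structured run.
    """
    if params.burst_b <= 1:
        raise ValueError("equilibrium density requires burst size b > 1")
    num = params.k_E * params.eps_fraction_E
    if params.k_I != 0 or params.k_D != 0 or params.debris_enabled:
        if I is None or D is None:
            raise ValueError(
                "k_I/k_D active: supply I and D for the generalized form "
                "(the result is approximate)")
        num = params.k_I * I + params.k_D * D + params.k_E * params.eps_fraction_E
    return num / (params.k_C * (params.burst_b - 1))


def amplification_Ag(C_obs: float, params: SimParams) -> tuple[float, float]:
    """Amplification of cell density over mass action, and its upper bound.

    Defined only when the causes of phage death are static: requires
    k_I = k_D = 0 and debris off. Returns (A_g, A_ub_g) with
    A_g = C_obs / C_hat and A_ub_g = 1 / C_hat.
    """
    if params.k_I != 0 or params.k_D != 0 or params.debris_enabled:
        raise ValueError(
            "A_g undefined with superinfection or debris active; report alpha*b")
    ch = c_hat(params)
    if ch <= 0:
        raise ValueError("C_hat is zero (no EPS): amplification undefined")
    return C_obs / ch, 1.0 / ch


def alpha_b_from_Ag(A_g: float, b: float) -> float:
    """Closed-form alpha*b implied by an amplification A_g at stationarity.

    With k_I = k_D = 0, substituting C = A_g * C_hat into alpha gives
    alpha*b = b * A_g / (A_g + b - 1). Used as a consistency check between
    the two reported statistics.
    """
    if A_g <= 0:
        raise ValueError("A_g must be positive")
    if b <= 1:
        raise ValueError("burst size must exceed 1")
    return b * A_g / (A_g + b - 1.0)


def summarize_window(series: Sequence[StepStats] | pd.DataFrame,
                     params: SimParams, mode: str = "spatial",
                     extinct: bool = False,
                     extinction_step: Optional[int] = None,
                     alpha_of_means: bool = False) -> RunSummary:
    """Average the trailing ``params.avg_window`` steps into a RunSummary.

    alpha*b is computed per step from instantaneous global densities and
    then averaged (set ``alpha_of_means`` to instead evaluate alpha at the
    window-mean densities). Per-burst losses P->X divide total window
    losses by total window bursts; C:E and P:E are window means of the
    per-step on-EPS fractions; I:E pools infections over the window.
    """
    df = series if isinstance(series, pd.DataFrame) else stats_to_frame(series)
    if len(df) == 0:
        raise ValueError("empty step series")
    win = min(params.avg_window, len(df))
    w = df.iloc[-win:]

    k = (params.k_C, params.k_I, params.k_D, params.k_E)
    den = (k[0] * w["C"] + k[1] * w["I"] + k[2] * w["D"]
           + k[3] * w["E"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ab_steps = np.where(den > 0, params.burst_b * k[0] * w["C"].to_numpy() / den,
                            np.nan)
    if alpha_of_means:
        mC, mI, mD = w["C"].mean(), w["I"].mean(), w["D"].mean()
        ab = params.burst_b * alpha(mC, mI, mD, params.eps_fraction_E, *k)
    else:
        ab = float(np.nanmean(ab_steps)) if np.any(np.isfinite(ab_steps)) else np.nan

    mean_C = float(w["C"].mean())
    A_g = A_ub = None
    if params.k_I == 0 and params.k_D == 0 and not params.debris_enabled \
            and params.burst_b > 1 and params.eps_fraction_E > 0:
        A_g, A_ub = amplification_Ag(mean_C, params)

    bursts = int(w["bursts"].sum())
    losses = {}
    for key, col in (("P_to_C", "loss_C"), ("P_to_I", "loss_I"),
                     ("P_to_E", "loss_E"), ("P_to_D", "loss_D")):
        losses[key] = float(w[col].sum()) / bursts if bursts > 0 else np.nan

    n_cells = w["n_uninfected"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_to_e = np.where(n_cells > 0, w["cells_on_eps"].to_numpy(float) / n_cells,
                          np.nan)
        p_tot = w["P"].to_numpy(float)
        p_to_e = np.where(p_tot > 0, w["phage_on_eps"].to_numpy(float) / p_tot,
                          np.nan)
    infections = int(w["loss_C"].sum())
    i_to_e = (float(w["infections_eps"].sum()) / infections
              if infections > 0 else np.nan)

    finite_ab = ab_steps[np.isfinite(ab_steps)]
    q10, q90 = (np.percentile(finite_ab, [10, 90]) if finite_ab.size
                else (np.nan, np.nan))

    return RunSummary(
        mode=mode,
        alpha_b=float(ab),
        A_g=A_g,
        A_ub_g=A_ub,
        mean_C=mean_C,
        mean_I=float(w["I"].mean()),
        mean_D=float(w["D"].mean()),
        mean_P=float(w["P"].mean()),
        C_on_E=float(np.nanmean(c_to_e)) if np.any(np.isfinite(c_to_e)) else np.nan,
        P_on_E=float(np.nanmean(p_to_e)) if np.any(np.isfinite(p_to_e)) else np.nan,
        I_on_E=i_to_e,
        loss_per_burst=losses,
        extinct=extinct,
        extinction_step=extinction_step,
        alpha_b_q10=float(q10),
        alpha_b_q90=float(q90),
        n_steps_run=len(df),
        window=win,
    )


_ENSEMBLE_MEANS = ("alpha_b", "A_g", "A_ub_g", "mean_C", "mean_I", "mean_D",
                   "mean_P", "C_on_E", "P_on_E", "I_on_E")


def summarize_ensemble(runs: Sequence[RunSummary]) -> dict:
    """Aggregate replicate runs into one table row.

    Means are over non-extinct runs only (extinct trials are excluded, as
    in the reported ensembles); the extinction count is reported
    separately. ``range_pct`` gives, per statistic, the range of the
    surviving runs' values as a percent of their mean — a spread
    diagnostic. If every run went extinct the row carries NaNs and the
    extinction count.
    """
    if not runs:
        raise ValueError("empty ensemble")
    survivors = [r for r in runs if not r.extinct]
    n_ext = len(runs) - len(survivors)
    row: dict = {"n_runs": len(runs), "n_extinct": n_ext}
    if not survivors:
        for name in _ENSEMBLE_MEANS:
            row[name] = np.nan
        for key in ("P_to_C", "P_to_I", "P_to_E", "P_to_D"):
            row[key] = np.nan
        row["range_pct"] = {}
        row["all_extinct"] = True
        return row
    row["all_extinct"] = False
    range_pct = {}
    for name in _ENSEMBLE_MEANS:
        vals = np.array([getattr(r, name) for r in survivors], dtype=float)
        if np.all(np.isnan(vals)):
            row[name] = np.nan
            continue
        m = float(np.nanmean(vals))
        row[name] = m
        if m != 0 and np.sum(np.isfinite(vals)) > 1:
            range_pct[name] = float(
                (np.nanmax(vals) - np.nanmin(vals)) / abs(m) * 100.0)
    for key in ("P_to_C", "P_to_I", "P_to_E", "P_to_D"):
        vals = np.array([r.loss_per_burst.get(key, np.nan) for r in survivors],
                        dtype=float)
        row[key] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
    row["range_pct"] = range_pct
    return row
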