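"""Phage diffusion kernel on the 3x3 Moore neighborhood.

Per-step phage movement follows a symmetric bivariate normal distribution
centered on the source patch, truncated to the patch and its eight
neighbors (unit squares). With F the standard normal CDF and

    A = 2 F(0.5/sigma) - 1        (probability mass over |x| <= 0.5)
    B = F(1.5/sigma) - F(0.5/sigma)

the unnormalized weights are A^2 for the center patch, A*B for each of the
four orthogonal neighbors and B^2 for each of the four diagonal neighbors;
they are normalized by A^2 + 4AB + 4B^2 so that all phage are accounted for
within the neighborhood.

Runs are usually parameterized by the *leave fraction* — the fraction of a
patch's phage that leaves the patch per step, 1 - w_center — which is
inverted to sigma by root finding. The leave fraction is bounded above by
8/9 (the sigma -> infinity limit where all nine weights tend to 1/9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["DiffusionKernel", "build_kernel", "sigma_from_leave_fraction", "MAX_LEAVE_FRACTION"]

#: Supremum of the per-step leave fraction attainable by the truncated kernel.
MAX_LEAVE_FRACTION = 8.0 / 9.0


@dataclass(frozen=True)
class DiffusionKernel:
    """Normalized 3x3 movement weights for free phage.

    Attributes
    ----------
    sigma : float
        Scale of the underlying bivariate normal, in patch widths.
    w_center, w_orth, w_diag : float
        Normalized probability of staying put, of moving to one given
        orthogonal neighbor, and to one given diagonal neighbor.
    norm : float
        The truncation mass A^2 + 4AB + 4B^2 before normalization.
    """

    sigma: float
    w_center: float
    w_orth: float
    w_diag: float
    norm: float

    @property
    def leave_fraction(self) -> float:
        """Expected fraction of a patch's phage leaving the patch per step."""
        return 1.0 - self.w_center

    def as_array(self) -> np.ndarray:
        """Return the kernel as a 3x3 array (row, col offsets -1..1)."""
        w = np.full((3, 3), self.w_diag)
        w[1, :] = w[:, 1] = self.w_orth
        w[1, 1] = self.w_center
        return w


def build_kernel(sigma: float) -> DiffusionKernel:
    """Build the normalized 3x3 diffusion kernel for scale ``sigma``.

    Parameters
    ----------
    sigma : float
        Positive scale of the truncated bivariate normal displacement.

    Returns
    -------
    DiffusionKernel
        Weights satisfying ``w_center + 4*w_orth + 4*w_diag == 1``.
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be positive and finite, got {sigma!r}")
    a = 2.0 * norm.cdf(0.5 / sigma) - 1.0
    b = norm.cdf(1.5 / sigma) - norm.cdf(0.5 / sigma)
    c = a * a + 4.0 * a * b + 4.0 * b * b
    return DiffusionKernel(
        sigma=float(sigma),
        w_center=a * a / c,
        w_orth=a * b / c,
        w_diag=b * b / c,
        norm=c,
    )


def sigma_from_leave_fraction(d: float) -> float:
    """Invert the kernel's leave fraction: find sigma with 1 - w_center == d.

    The map sigma -> leave fraction is a monotone bijection from (0, inf)
    onto (0, 8/9), so ``d`` must lie strictly inside that interval.
    """
    if not (0.0 < d < MAX_LEAVE_FRACTION):
        raise ValueError(
            f"leave fraction must be in (0, {MAX_LEAVE_FRACTION:.6f}); got {d!r}"
        )

    def f(s: float) -> float:
        return build_kernel(s).leave_fraction - d

    lo, hi = 1e-3, 1.0
    while f(lo) > 0:
        lo /= 4.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for d < 8/9
            raise RuntimeError("failed to bracket sigma")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))
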