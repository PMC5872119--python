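"""Parameterization of one lattice run.

A run is fully specified by geometry (width x height torus), phage biology
(burst size, adsorption probabilities, infected lifespan), the EPS phage
sink (fraction of patches and layout), optional lysed-cell debris, cell
reproduction, phage diffusion, run length / averaging window, initial
occupancy fractions and the RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import yaml

from .kernel import MAX_LEAVE_FRACTION, build_kernel, sigma_from_leave_fraction

__all__ = ["SimParams"]

_PROB_FIELDS = ("eps_fraction_E", "k_C", "k_I", "k_D", "k_E", "cell_repro_prob",
                "init_cell_frac", "init_phage_frac")


@dataclass(frozen=True)
class SimParams:
    """Full parameter set for one spatial or mass-action grid run.

    Adsorption probabilities are per phage per step: ``k_C`` to uninfected
    cells, ``k_I`` to infected cells (superinfection, a pure phage loss),
    ``k_D`` to lysed-cell debris and ``k_E`` to EPS. Diffusion is given
    either as ``diffuse_fraction`` (per-step fraction of a patch's phage
    that leaves the patch, as reported in run descriptions) or directly as
    the kernel scale ``sigma``; exactly one may be set.
    """

    width: int = 100
    height: int = 100
    burst_b: int = 10
    eps_fraction_E: float = 0.3
    eps_layout: str = "random"  # "random" | "clustered_rows"
    k_C: float = 0.25
    k_I: float = 0.0
    k_D: float = 0.0
    k_E: float = 0.35
    cell_repro_prob: float = 0.1
    diffuse_fraction: Optional[float] = 0.3
    sigma: Optional[float] = None
    infected_lifespan: int = 20
    debris_enabled: bool = False
    debris_lifespan: int = 2
    n_steps: int = 10_000
    avg_window: int = 3_000
    init_cell_frac: float = 0.3
    init_phage_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.burst_b < 1:
            raise ValueError("burst size must be >= 1")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {v!r}")
        if self.eps_layout not in ("random", "clustered_rows"):
            raise ValueError(f"unknown eps_layout {self.eps_layout!r}")
        if (self.diffuse_fraction is None) == (self.sigma is None):
            raise ValueError("set exactly one of diffuse_fraction and sigma")
        if self.diffuse_fraction is not None and not (
            0.0 <= self.diffuse_fraction < MAX_LEAVE_FRACTION
        ):
            raise ValueError(
                f"diffuse_fraction must be in [0, {MAX_LEAVE_FRACTION:.6f})"
            )
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.infected_lifespan < 1:
            raise ValueError("infected_lifespan must be >= 1")
        if self.debris_lifespan < 1:
            raise ValueError("debris_lifespan must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (1 <= self.avg_window <= self.n_steps):
            raise ValueError("avg_window must be in [1, n_steps]")

    @property
    def n_patches(self) -> int:
        return self.width * self.height

    def resolve_sigma(self) -> Optional[float]:
        """Kernel scale, inverting the leave fraction if needed.

        Returns None for ``diffuse_fraction == 0`` (no movement at all; a
        degenerate identity kernel is used downstream).
        """
        if self.sigma is not None:
            return self.sigma
        if self.diffuse_fraction == 0.0:
            return None
        return sigma_from_leave_fraction(self.diffuse_fraction)

    def kernel(self):
        """The diffusion kernel for this parameter set (None if immobile)."""
        s = self.resolve_sigma()
        return None if s is None else build_kernel(s)

    def with_updates(self, **kw) -> "SimParams":
        """Return a copy with the given fields replaced (re-validated)."""
        if "sigma" in kw and kw["sigma"] is not None and "diffuse_fraction" not in kw:
            kw["diffuse_fraction"] = None
        if ("diffuse_fraction" in kw and kw["diffuse_fraction"] is not None
                and "sigma" not in kw):
            kw["sigma"] = None
        return replace(self, **kw)

    # -- config file round trip -------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        if d.get("sigma") is not None and "diffuse_fraction" not in d:
            d = {**d, "diffuse_fraction": None}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
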