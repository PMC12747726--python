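"""Blood rheology: Newtonian and shear-thinning viscosity laws.

Whole blood is shear-thinning: its apparent dynamic viscosity falls from a
zero-shear plateau (rouleaux aggregation) toward an infinite-shear plateau
as the shear rate γ̇ grows.  Four laws are provided:

* ``newtonian`` — constant viscosity μ (default 0.004 Pa·s);
* ``carreau_yasuda`` — η(γ̇) = η∞ + (η0 − η∞)·(1 + (λγ̇)^a)^((n−1)/a),
  with η0 = 0.16 Pa·s, η∞ = 0.004 Pa·s, λ = 8.2 s, a = 0.64, n = 0.2128;
* ``casson`` — yield-stress law η(γ̇) = (√(τ0/γ̇) + √η_c)², closed over
  hematocrit H via the Merrill relations τ0 = 0.1·(0.625·H)³ Pa and
  η_c = η_plasma·(1 − H)^(−2.5);
* ``herschel_bulkley`` — η(γ̇) = τ0/γ̇ + k·(γ̇/γ̇c)^(n−1), with
  τ0 = 0.01 Pa, k = 0.04, n = 0.7, γ̇c = 0.001 s⁻¹.

The Casson and Herschel–Bulkley laws diverge as γ̇ → 0; evaluations clamp
γ̇ from below (``gamma_floor``, default 1e−6 s⁻¹) so viscosity fields stay
finite, mirroring the internal clipping of production CFD solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

ModelName = Literal["newtonian", "carreau_yasuda", "casson", "herschel_bulkley"]

#: Short CLI aliases for the four laws.
MODEL_ALIASES = {
    "newtonian": "newtonian",
    "cy": "carreau_yasuda",
    "carreau_yasuda": "carreau_yasuda",
    "casson": "casson",
    "hb": "herschel_bulkley",
    "herschel_bulkley": "herschel_bulkley",
}


@dataclass(frozen=True)
class RheologyParams:
    """Parameters of one blood viscosity law.

    Only the fields relevant to ``model`` are used; defaults reproduce the
    standard literature parameterisations for human blood.
    """

    model: ModelName = "newtonian"
    mu: float = 0.004            # Newtonian dynamic viscosity, Pa·s
    eta0: float = 0.16           # zero-shear viscosity, Pa·s
    eta_inf: float = 0.004       # infinite-shear viscosity, Pa·s
    lam: float = 8.2             # Carreau-Yasuda time constant, s
    a: float = 0.64              # Yasuda exponent
    n: float = 0.2128            # power-law index (0.2128 CY, 0.7 HB)
    tau0: float = 0.01           # yield stress, Pa (HB)
    k: float = 0.04              # consistency index, kg·s^(n-2)·m^(-1) (HB)
    gammac: float = 0.001        # critical shear rate, s^(-1) (HB)
    hematocrit: float = 0.40     # red-cell volume fraction (Casson)
    plasma_viscosity: float = 0.0014  # Pa·s (Casson)
    rho: float = 1050.0          # blood density, kg/m^3
    gamma_floor: float = 1e-6    # clamp for diverging laws, s^(-1)

    def __post_init__(self) -> None:
        if self.model not in ("newtonian", "carreau_yasuda", "casson", "herschel_bulkley"):
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("mu", "eta0", "eta_inf", "lam", "a", "gammac", "rho",
                     "plasma_viscosity", "gamma_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.eta0 < self.eta_inf:
            raise ValueError("eta0 must be >= eta_inf")

    # Merrill hematocrit closure for the Casson law
    @property
    def casson_yield_stress(self) -> float:
        """Casson yield stress τ0 = 0.1·(0.625·H)³, Pa."""
        return 0.1 * (0.625 * self.hematocrit) ** 3

    @property
    def casson_viscosity(self) -> float:
        """Casson asymptotic viscosity η_c = η_plasma·(1−H)^(−2.5), Pa·s."""
        return self.plasma_viscosity * (1.0 - self.hematocrit) ** -2.5

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RheologyParams":
        return cls(**d)


def viscosity(params: RheologyParams, gamma_dot) -> np.ndarray | float:
    """Dynamic viscosity η(γ̇), Pa·s, for the selected law.

    Vectorised over arrays of shear rates.  Negative or non-finite shear
    rates are rejected; for the diverging Casson/Herschel–Bulkley laws,
    γ̇ is clamped below at ``params.gamma_floor``.
    """
    g = np.asarray(gamma_dot, dtype=float)
    scalar = g.ndim == 0
    if not np.all(np.isfinite(g)):
        raise ValueError("shear rates must be finite")
    if np.any(g < 0):
        raise ValueError("shear rates must be non-negative")

    if params.model == "newtonian":
        eta = np.full_like(g, params.mu)
    elif params.model == "carreau_yasuda":
        eta = params.eta_inf + (params.eta0 - params.eta_inf) * (
            1.0 + (params.lam * g) ** params.a
        ) ** ((params.n - 1.0) / params.a)
    elif params.model == "casson":
        gc = np.maximum(g, params.gamma_floor)
        eta = (np.sqrt(params.casson_yield_stress / gc)
               + np.sqrt(params.casson_viscosity)) ** 2
    else:  # herschel_bulkley
        gc = np.maximum(g, params.gamma_floor)
        eta = params.tau0 / gc + params.k * (gc / params.gammac) ** (params.n - 1.0)
    return float(eta) if scalar else eta


def strain_rate_magnitude(velocity_field: np.ndarray, spacing: float) -> np.ndarray:
    """Shear-rate magnitude γ̇ = √(2 S:S) from a velocity field, s⁻¹.

    ``velocity_field`` has shape (nx, ny, nz, 3) with velocities in mm/s;
    ``spacing`` is the isotropic voxel size in mm, so γ̇ comes out in s⁻¹.
    S is the symmetric part of the velocity-gradient tensor, assembled
    from central differences (one-sided at the array boundary).
    """
    v = np.asarray(velocity_field, dtype=float)
    if v.ndim != 4 or v.shape[-1] != 3:
        raise ValueError("velocity_field must have shape (nx, ny, nz, 3)")
    if min(v.shape[:3]) < 3:
        raise ValueError("need at least 3 voxels per axis")
    # J[i, j] = d v_i / d x_j
    ss = np.zeros(v.shape[:3])
    grads = [np.gradient(v[..., i], spacing, axis=(0, 1, 2)) for i in range(3)]
    for i in range(3):
        for j in range(3):
            s_ij = 0.5 * (grads[i][j] + grads[j][i])
            ss += s_ij * s_ij
    return np.sqrt(2.0 * ss)


def reynolds_number(params: RheologyParams, flow_rate: float, diameter: float,
                    viscosity_value: float | None = None) -> float:
    """Pipe Reynolds number Re = 4 ρ Q / (π μ D).

    ``flow_rate`` in m³/s, ``diameter`` in m; ``viscosity_value`` defaults
    to the law's infinite-shear viscosity (Newtonian μ for the Newtonian
    law).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if flow_rate < 0:
        raise ValueError("flow rate must be non-negative")
    if viscosity_value is None:
        viscosity_value = params.mu if params.model == "newtonian" else params.eta_inf
    if viscosity_value <= 0:
        raise ValueError("viscosity must be positive")
    return 4.0 * params.rho * flow_rate / (np.pi * viscosity_value * diameter)
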