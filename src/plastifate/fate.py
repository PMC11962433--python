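"""Two-compartment marine fate model and steady-state fate factors.

Compartments: the water column (emission target; surface water is collapsed
into it) and the surficial sediment. First-order processes, all in 1/day:

- degradation in water and in sediment (from the SSDR and particle geometry),
- sedimentation (water → sediment),
- resuspension (sediment → water),
- deep burial (sediment → permanent loss).

With the rate matrix K (sign convention dX/dt = −K·X + emission) the fate
factor vector is the steady-state residence time τ = K⁻¹·e per unit emission
rate, equal to the time-integrated mass of a unit pulse. FF_water and
FF_sediment are in days.

The mapping from a surface recession velocity v_d to a first-order rate is the
initial-rate equivalent of the shrinking-particle model: a particle losing
Δm/m0 = 1 − (1 − 2·v_d·t/d0)^a has d(ln m)/dt = −2·a·v_d/d0 at t = 0, i.e.
k_deg = 6 v_d/d0 for spheres, 4 v_d/d0 for fibers and 2 v_d/d0 for films
(two-sided recession of a slab of thickness d0).

Numeric transfer/loss rates are site- and density-specific and are not fixed
by this package; :data:`DEMO_FATE_PARAMETERS` ships clearly-labelled
placeholder values for demonstration and testing only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InfiniteResidenceError
from .ssdr import ParticleGeometry

__all__ = [
    "FateParameters", "FateFactors", "DEMO_FATE_PARAMETERS",
    "degradation_rate_constant", "build_rate_matrix",
    "steady_state_fate_factors", "transient_oracle", "fate_factors",
]


@dataclass(frozen=True)
class FateParameters:
    """First-order transfer/loss rates of the two-compartment model.

    Units: all ``k_*`` in 1/day, SSDRs in µm/day. ``ssdr_sediment`` defaults
    to the water-column value (no sediment-specific degradation data)."""

    k_sed: float                    # water → sediment, 1/day
    k_resusp: float                 # sediment → water, 1/day
    k_burial: float                 # sediment → deep loss, 1/day
    ssdr_water: float               # µm/day
    ssdr_sediment: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        for name in ("k_sed", "k_resusp", "k_burial", "ssdr_water"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ssdr_sediment is None:
            object.__setattr__(self, "ssdr_sediment", self.ssdr_water)
        elif self.ssdr_sediment < 0:
            raise ValueError("ssdr_sediment must be >= 0")


#: placeholder rates for demonstration/testing; sedimentation fast (high
#: density polymers), resuspension and burial orders of magnitude slower
DEMO_FATE_PARAMETERS = FateParameters(
    k_sed=0.4, k_resusp=1e-3, k_burial=2e-3, ssdr_water=0.1,
    note="demo placeholder rates, not site-calibrated",
)


@dataclass(frozen=True)
class FateFactors:
    """Time-integrated mass residence (days) per unit emission to water."""

    ff_water: float
    ff_sediment: float
    emission_compartment: str = "water"


def degradation_rate_constant(vd: float, geometry: ParticleGeometry) -> float:
    """First-order degradation rate (1/day) for a particle of this geometry
    eroding at ``vd`` µm/day (initial-rate equivalent, k = 2·a·v_d/d0)."""
    if vd < 0:
        raise ValueError(f"vd must be >= 0, got {vd}")
    return 2.0 * geometry.shape_exponent_a * vd / geometry.d0


def build_rate_matrix(params: FateParameters, k_deg_water: float,
                      k_deg_sediment: float) -> np.ndarray:
    """Assemble the 2×2 loss/transfer matrix K, rows = (water, sediment).

    dX/dt = −K·X + emission, with
    K = [[k_deg_w + k_sed,      −k_resusp              ],
         [−k_sed,               k_deg_s + k_resusp + k_burial]]
    """
    if k_deg_water < 0 or k_deg_sediment < 0:
        raise ValueError("degradation rate constants must be >= 0")
    return np.array([
        [k_deg_water + params.k_sed, -params.k_resusp],
        [-params.k_sed, k_deg_sediment + params.k_resusp + params.k_burial],
    ])


def _diagnose_singular(K: np.ndarray) -> str:
    k_sed = -K[1, 0]
    k_resusp = -K[0, 1]
    water_loss = K[0, 0] - 0.0          # k_deg_w + k_sed
    sed_sink = K[1, 1] - k_resusp       # k_deg_s + k_burial
    if water_loss == 0:
        return ("water column has no loss pathway "
                "(degradation and sedimentation both zero)")
    if k_sed > 0 and sed_sink == 0:
        return ("sediment has no sink (degradation and burial both zero); "
                "mass cycles in the water–sediment loop forever"
                if k_resusp > 0 else
                "sediment has no sink (degradation and burial both zero)")
    return "rate matrix is singular"


def steady_state_fate_factors(K: np.ndarray, emission=(1.0, 0.0)) -> FateFactors:
    """Fate factors from the steady-state solution τ = K⁻¹·e.

    Equals the time-integral of the transient decay of a unit pulse (checked
    against :func:`transient_oracle`). Raises
    :class:`InfiniteResidenceError` when K is singular, naming the closed
    loop without a loss pathway.
    """
    K = np.asarray(K, dtype=float)
    e = np.asarray(emission, dtype=float)
    # sediment unreachable (no sedimentation, no direct emission): the model
    # degenerates to a single water compartment even though K is singular
    if K[1, 0] == 0 and e[1] == 0:
        if K[0, 0] <= 0:
            raise InfiniteResidenceError(_diagnose_singular(K))
        return FateFactors(ff_water=float(e[0] / K[0, 0]), ff_sediment=0.0)
    det = K[0, 0] * K[1, 1] - K[0, 1] * K[1, 0]
    scale = max(abs(K).max(), 1.0)
    if det <= 1e-15 * scale ** 2:
        raise InfiniteResidenceError(_diagnose_singular(K))
    tau = np.linalg.solve(K, e)
    return FateFactors(ff_water=float(tau[0]), ff_sediment=float(tau[1]))


def transient_oracle(K: np.ndarray, emission=(1.0, 0.0), horizon: float | None = None,
                     step: float | None = None) -> FateFactors:
    """Fate factors by numerically integrating the pulse decay.

    Integrates dX/dt = −K·X from X(0) = emission and accumulates ∫X dt over
    ``horizon`` days (default 50 divided by the smallest positive rate).
    Serves as an independent check of :func:`steady_state_fate_factors`;
    warns when mass remaining at the horizon exceeds 1e-6 of the pulse.
    """
    K = np.asarray(K, dtype=float)
    e = np.asarray(emission, dtype=float)
    if not e.any():
        return FateFactors(ff_water=0.0, ff_sediment=0.0)
    if horizon is None:
        # slowest decay mode sets the time scale
        lam = np.linalg.eigvals(K).real
        if lam.min() <= 0:
            raise InfiniteResidenceError(
                "rate matrix has a non-decaying mode: no finite horizon")
        horizon = 50.0 / lam.min()

    def rhs(_t, y):
        x = y[:2]
        return np.concatenate([-K @ x, x])

    sol = solve_ivp(rhs, (0.0, horizon), np.concatenate([e, [0.0, 0.0]]),
                    method="LSODA", rtol=1e-9, atol=1e-14,
                    max_step=step if step is not None else np.inf)
    remaining = sol.y[:2, -1].sum()
    if remaining > 1e-6 * e.sum():
        import warnings
        warnings.warn(
            f"transient integration truncated: {remaining:.3g} of the unit "
            f"pulse remains at horizon {horizon:g} d; fate factors are "
            "underestimates", stacklevel=2)
    return FateFactors(ff_water=float(sol.y[2, -1]), ff_sediment=float(sol.y[3, -1]))


def fate_factors(params: FateParameters, geometry: ParticleGeometry) -> FateFactors:
    """Convenience chain: geometry + rates → K → steady-state fate factors."""
    k_w = degradation_rate_constant(params.ssdr_water, geometry)
    k_s = degradation_rate_constant(params.ssdr_sediment, geometry)
    K = build_rate_matrix(params, k_w, k_s)
    return steady_state_fate_factors(K)
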