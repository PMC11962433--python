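"""Specific surface degradation rates (SSDR) from mass-loss fractions.

Under the surface-erosion assumption a particle degrades by front recession
only, so the observed relative mass loss Δm/m0 after incubation time t maps to
a recession velocity

    v_d = (1/2) · (d0/t) · (1 − (1 − Δm/m0)^(1/a))

with d0 the initial characteristic length (diameter for spheres and fibers,
thickness for films) and a the shape exponent (3, 2, 1 respectively). v_d is
evaluated natively in µm/yr; :data:`UM_PER_YR_TO_UM_PER_DAY` converts for the
fate model.

A mass-loss correction for transferring macro-scale degradation observations
to micro scale is provided as an explicit opt-in transform
(:func:`corrected_mass_loss`); it is a conservative, material-specific
approximation and is never applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CompleteDegradationError
from .biodeg import DegradationCurve
from .synthetic import DAYS_PER_YEAR

UM_PER_YR_TO_UM_PER_DAY = 1.0 / DAYS_PER_YEAR

#: shape → exponent of the shrinking-length mass relation
SHAPE_EXPONENT = {"sphere": 3, "fiber": 2, "film": 1}


@dataclass(frozen=True)
class ParticleGeometry:
    """Shape and characteristic size of a particle population.

    ``d0`` is the diameter for spheres and fibers and the thickness for films,
    in µm. The shape exponent is the number of dimensions along which the
    erosion front shrinks the particle.
    """

    shape: str
    d0: float

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_EXPONENT:
            raise ValueError(
                f"shape must be one of {sorted(SHAPE_EXPONENT)}, got {self.shape!r}")
        if self.d0 <= 0:
            raise ValueError(f"d0 must be positive, got {self.d0}")

    @property
    def shape_exponent_a(self) -> int:
        return SHAPE_EXPONENT[self.shape]


@dataclass
class SSDREstimate:
    """A surface degradation velocity with its provenance."""

    polymer_id: str
    vd: float                        # µm/yr
    geometry: ParticleGeometry | None = None
    incubation_time: float = float("nan")   # yr
    deg_fraction: float = float("nan")
    replicate_values: list[float] = field(default_factory=list)
    method_note: str = ""

    @property
    def vd_sd(self) -> float:
        """Sample sd over replicate SSDRs (nan when < 2 replicates)."""
        if len(self.replicate_values) < 2:
            return float("nan")
        return float(np.std(self.replicate_values, ddof=1))


def ssdr_from_mass_loss(deg_fraction: float, d0: float, a: int, t_yr: float) -> float:
    """Invert the shrinking-particle relation for the surface velocity (µm/yr).

    Raises :class:`CompleteDegradationError` for a fully degraded sample
    (Δm/m0 ≥ 1): the velocity is then only bounded from below.
    """
    if d0 <= 0 or t_yr <= 0:
        raise ValueError(f"d0 and t must be positive, got d0={d0}, t={t_yr}")
    if a not in (1, 2, 3):
        raise ValueError(f"shape exponent a must be 1, 2 or 3, got {a}")
    if deg_fraction < 0:
        raise ValueError(f"deg_fraction must be >= 0, got {deg_fraction}")
    if deg_fraction >= 1:
        raise CompleteDegradationError(
            "mass loss is complete; the SSDR is a lower bound "
            f"(>= {0.5 * d0 / t_yr:.4g} µm/yr), not a point estimate")
    return 0.5 * (d0 / t_yr) * (1.0 - (1.0 - deg_fraction) ** (1.0 / a))


def correction_factor(ds: float, dl: float) -> float:
    """Downscaling factor (ds/dl)^(2/3) for macro→micro mass-loss transfer.

    ``ds`` and ``dl`` are the initial diameters of the smaller (target) and
    larger (observed) particles. Defined for downscaling only (ds ≤ dl)."""
    if ds <= 0 or dl <= 0:
        raise ValueError("diameters must be positive")
    if ds > dl:
        raise ValueError(
            f"correction factor is defined for downscaling only (ds <= dl), "
            f"got ds={ds} > dl={dl}")
    return (ds / dl) ** (2.0 / 3.0)


def corrected_mass_loss(mass_loss_large: float, ds: float, dl: float) -> float:
    """Scale a macro-particle mass loss down to a micro-particle estimate.

    The result feeds :func:`ssdr_from_mass_loss` with ``d0 = ds``. It is a
    conservative approximation, not a physical mass balance, validated only
    for the polymer it was derived on — hence an explicit opt-in step."""
    if not 0 <= mass_loss_large <= 1:
        raise ValueError(
            f"mass_loss_large must be in [0, 1], got {mass_loss_large}")
    return correction_factor(ds, dl) * mass_loss_large


def aggregate_ssdr(estimates, method: str = "geometric_mean") -> SSDREstimate:
    """Aggregate several SSDR estimates of one polymer into a single rate.

    The geometric mean is used (rates span orders of magnitude across
    conditions). Accepts :class:`SSDREstimate` objects or bare values; all
    must share a polymer id and be strictly positive.
    """
    if method != "geometric_mean":
        raise ValueError(f"unknown aggregation method {method!r}")
    items = list(estimates)
    if not items:
        raise ValueError("cannot aggregate an empty collection of estimates")
    if isinstance(items[0], SSDREstimate):
        polymer_ids = {e.polymer_id for e in items}
        if len(polymer_ids) > 1:
            raise ValueError(
                f"estimates mix polymers {sorted(polymer_ids)}; aggregate one "
                "polymer at a time")
        polymer_id = items[0].polymer_id
        values = [e.vd for e in items]
    else:
        polymer_id = ""
        values = [float(v) for v in items]
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValueError(
            "geometric mean undefined for non-positive SSDRs: "
            f"{arr[arr <= 0].tolist()}")
    vd = float(np.exp(np.mean(np.log(arr))))
    return SSDREstimate(
        polymer_id=polymer_id, vd=vd, replicate_values=values,
        method_note=f"geometric mean of {len(values)} estimates")


def estimate_from_curve(
    curve: DegradationCurve,
    geometry: ParticleGeometry,
    mode: str = "per_replicate",
) -> SSDREstimate:
    """Estimate the SSDR of one polymer from its degradation curve.

    Uses the final sampling point. ``per_replicate`` (default) inverts each
    replicate's final degradation fraction and reports the arithmetic mean
    with the per-replicate values retained; ``mean_deg`` inverts the
    triplicate-mean fraction directly.
    """
    t_yr = float(curve.times[-1]) / DAYS_PER_YEAR
    a = geometry.shape_exponent_a
    if mode == "per_replicate":
        if curve.replicate_deg is None:
            raise ValueError("curve carries no per-replicate fractions")
        reps = [
            ssdr_from_mass_loss(float(d), geometry.d0, a, t_yr)
            for d in curve.replicate_deg[:, -1]
        ]
        vd = float(np.mean(reps))
    elif mode == "mean_deg":
        reps = []
        vd = ssdr_from_mass_loss(curve.final(), geometry.d0, a, t_yr)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SSDREstimate(
        polymer_id=curve.polymer_id, vd=vd, geometry=geometry,
        incubation_time=t_yr, deg_fraction=curve.final(),
        replicate_values=reps, method_note=f"mode={mode}, final time point")
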