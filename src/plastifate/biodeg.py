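"""Reduction of flask-level CO2 series to biodegradation fractions.

The degradation fraction of a sample at time t is the blank-corrected CO2
evolved divided by the theoretical CO2 of complete mineralisation:

    Deg_i(t) = (m_CO2,i(t) − m_CO2,blank(t)) / ThCO2_i
    ThCO2_i  = m0_i · C_tot · 44/12

Blanks capture the intrinsic oxidation activity of the seawater inoculum; the
abiotic (poisoned) control is a QC channel verifying that CO2 production is
microbial, and is never subtracted into the samples. Carbon fixed as biomass
is neglected in the balance (an error usually below 5–10 %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NegativeSignalWarning
from .synthetic import CO2_PER_CARBON

__all__ = [
    "PolymerSpec", "DegradationCurve", "DEFAULT_POLYMERS",
    "theoretical_co2", "degradation_fraction", "build_degradation_curves",
]


@dataclass(frozen=True)
class PolymerSpec:
    """Static polymer properties used in the carbon balance."""

    polymer_id: str
    c_tot: float                    # total carbon mass fraction, 0–1
    density_class: str = "high"     # {high, medium, low} (settling behaviour)
    grade: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.c_tot <= 1:
            raise ValueError(f"c_tot must be in (0, 1], got {self.c_tot}")
        if self.density_class not in ("high", "medium", "low"):
            raise ValueError(f"unknown density_class {self.density_class!r}")


#: total organic carbon contents of the studied polyesters; all three are
#: denser than 1.1 g/cm3 and settle (high-density group)
DEFAULT_POLYMERS: dict[str, PolymerSpec] = {
    "PCL": PolymerSpec("PCL", 0.454),
    "PLA": PolymerSpec("PLA", 0.493),
    "PBSA": PolymerSpec("PBSA", 0.52),
}


@dataclass
class DegradationCurve:
    """Triplicate-summarised degradation fraction over time for one condition."""

    polymer_id: str
    times: np.ndarray               # days
    deg_mean: np.ndarray            # fraction, per time point
    deg_sd: np.ndarray              # sample sd over replicates
    n_replicates: int
    replicate_deg: np.ndarray = field(repr=False, default=None)  # (n_rep, n_t)
    temperature_c: float = float("nan")
    clamped: bool = False           # any negative blank-corrected value clamped

    def final(self) -> float:
        """Mean degradation fraction at the last sampling time."""
        return float(self.deg_mean[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "polymer_id": self.polymer_id,
            "temperature_c": self.temperature_c,
            "time_days": self.times,
            "deg_mean": self.deg_mean,
            "deg_sd": self.deg_sd,
            "n_replicates": self.n_replicates,
        })


def theoretical_co2(m0: float, c_tot: float) -> float:
    """Theoretical CO2 mass (mg) from complete mineralisation of ``m0`` mg of
    polymer with carbon fraction ``c_tot`` (44/12 converts carbon to CO2)."""
    if m0 <= 0:
        raise ValueError(f"m0 must be positive, got {m0}")
    if not 0 < c_tot <= 1:
        raise ValueError(f"c_tot must be in (0, 1], got {c_tot}")
    return m0 * c_tot * CO2_PER_CARBON


def degradation_fraction(sample_co2: float, blank_co2: float, th_co2: float) -> float:
    """Blank-corrected degradation fraction (sample − blank)/ThCO2.

    Negative corrected signals (sample below blank, possible early in the
    incubation when the signal is within noise) are clamped to 0 and flagged
    with :class:`NegativeSignalWarning`; values above 1 are reported as-is.
    """
    if th_co2 <= 0:
        raise ValueError(f"th_co2 must be positive, got {th_co2}")
    deg = (sample_co2 - blank_co2) / th_co2
    if deg < 0:
        warnings.warn(
            f"blank-corrected CO2 signal {sample_co2 - blank_co2:.3g} mg is "
            "negative; degradation clamped to 0", NegativeSignalWarning,
            stacklevel=2)
        return 0.0
    return deg


def _mean_blank(series: pd.DataFrame, sample_times: np.ndarray) -> np.ndarray:
    """Mean blank CO2 interpolated linearly onto the sample time grid."""
    blanks = series[series["role"] == "blank"]
    if blanks.empty:
        raise ValueError("no blank flasks present in the incubation table")
    mean = blanks.groupby("time_days")["co2_mg"].mean()
    return np.interp(sample_times, mean.index.to_numpy(), mean.to_numpy())


def build_degradation_curves(
    series: pd.DataFrame,
    polymers: dict[str, PolymerSpec] | None = None,
) -> dict[str, DegradationCurve]:
    """Reduce a tidy incubation table to one degradation curve per condition.

    Groups sample flasks by (polymer_id, temperature), subtracts the mean
    blank (interpolated onto the sample grid when the grids differ), divides
    by each flask's theoretical CO2, and summarises replicates with the
    arithmetic mean and sample standard deviation. Per-replicate fractions are
    retained on the curve for uncertainty propagation. Abiotic flasks are
    ignored here (QC only; see :func:`abiotic_qc`).

    Returns a dict keyed by ``polymer_id`` (or ``polymer_id@T`` when one
    polymer appears at several temperatures).
    """
    polymers = polymers if polymers is not None else DEFAULT_POLYMERS
    samples = series[series["role"] == "sample"]
    if samples.empty:
        raise ValueError("no sample flasks present in the incubation table")

    curves: dict[str, DegradationCurve] = {}
    grouped = samples.groupby(["polymer_id", "temperature_c"])
    multi_t = samples.groupby("polymer_id")["temperature_c"].nunique()
    for (polymer_id, temp), grp in grouped:
        if polymer_id not in polymers:
            raise KeyError(
                f"polymer {polymer_id!r} not in the polymer property table "
                f"(known: {sorted(polymers)})")
        spec = polymers[polymer_id]
        rep_curves = []
        times_ref = None
        clamped = False
        for _, flask in grp.groupby("flask_id"):
            flask = flask.sort_values("time_days")
            times = flask["time_days"].to_numpy(dtype=float)
            if times_ref is None:
                times_ref = times
            elif not np.allclose(times, times_ref):
                raise ValueError(
                    f"replicate flasks of {polymer_id} have mismatched time grids")
            blank = _mean_blank(series, times)
            th = theoretical_co2(float(flask["m0_mg"].iloc[0]), spec.c_tot)
            deg = (flask["co2_mg"].to_numpy(dtype=float) - blank) / th
            if (deg < 0).any():
                clamped = True
                deg = np.clip(deg, 0.0, None)
            rep_curves.append(deg)
        rep = np.vstack(rep_curves)
        if clamped:
            warnings.warn(
                f"{polymer_id}: negative blank-corrected values clamped to 0",
                NegativeSignalWarning, stacklevel=2)
        key = polymer_id if multi_t[polymer_id] == 1 else f"{polymer_id}@{temp:g}C"
        curves[key] = DegradationCurve(
            polymer_id=polymer_id,
            times=times_ref,
            deg_mean=rep.mean(axis=0),
            deg_sd=rep.std(axis=0, ddof=1) if rep.shape[0] > 1 else np.zeros(rep.shape[1]),
            n_replicates=rep.shape[0],
            replicate_deg=rep,
            temperature_c=float(temp),
            clamped=clamped,
        )
    return curves


def abiotic_qc(series: pd.DataFrame) -> pd.DataFrame:
    """Blank-corrected signal of the abiotic controls, as a QC table.

    For a valid experiment the corrected abiotic signal should be zero within
    noise (no non-microbial CO2 source)."""
    abiotic = series[series["role"] == "abiotic"]
    out = []
    for flask_id, flask in abiotic.groupby("flask_id"):
        flask = flask.sort_values("time_days")
        times = flask["time_days"].to_numpy(dtype=float)
        blank = _mean_blank(series, times)
        out.append(pd.DataFrame({
            "flask_id": flask_id,
            "time_days": times,
            "corrected_co2_mg": flask["co2_mg"].to_numpy(dtype=float) - blank,
        }))
    if not out:
        return pd.DataFrame(columns=["flask_id", "time_days", "corrected_co2_mg"])
    return pd.concat(out, ignore_index=True)
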