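"""Midpoint and endpoint characterization factors for physical effects on
biota, and the canonical polymer CF dataset.

A midpoint characterization factor combines the fate factors with
compartment-level exposure-effect factors (EEFs):

    midpoint CF = FF_water·EEF_water + FF_sediment·EEF_sediment
                  [PAF·m³·day/kg emitted]

The endpoint CF converts the potentially affected fraction to potentially
disappeared fraction via a severity factor and normalises by water depth,

    endpoint CF = midpoint CF · SF / depth / 365   [PDF·m²·yr/kg emitted]

(the day→yr conversion is explicit here), and the ReCiPe-compatible damage
score multiplies by a marine species density and a reference depth:

    species·yr/kg = endpoint CF · 3.46e-12 species/m³ · 100 m.

The packaged canonical dataset covers three biodegradable polyesters (PCL,
PLA, PBSA) × three shapes × five sizes (1–5000 µm) at both levels. EEFs and
the severity factor behind it are not public; the default SF/depth pair below
is calibrated to the constant endpoint/midpoint ratio of the canonical table
(≈ 2.72e-5) and is a calibration, not a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .errors import CanonicalLookupError
from .fate import FateFactors

__all__ = [
    "EffectParameters", "load_canonical_cfs", "canonical_cf_lookup",
    "midpoint_cf", "endpoint_cf", "recipe_species_yr",
    "comparative_metrics", "validate_canonical_dataset", "compute_cf_records",
]

POLYMERS = ("PCL", "PLA", "PBSA")
SHAPES = ("sphere", "fiber", "film")
SIZES_UM = (1, 10, 100, 1000, 5000)

_LEVEL_COLUMN = {
    "midpoint": "midpoint_paf_m3_day_per_kg",
    "endpoint": "endpoint_pdf_m2_yr_per_kg",
}


@dataclass(frozen=True)
class EffectParameters:
    """Exposure-effect and conversion constants of the CF chain.

    ``eef_water``/``eef_sediment`` are in PAF·m³/kg per day of residence.
    The shipped values are demonstration placeholders (the underlying
    EC10-based EEFs are not public). ``severity_factor`` (PDF/PAF) and
    ``water_depth`` (m) enter only through their ratio; the defaults are
    calibrated so that endpoint/midpoint = SF/depth/365 ≈ 2.72e-5,
    matching the canonical dataset. ``species_density`` (species/m³) and
    ``depth_for_recipe`` (m) are the published damage-conversion constants.
    """

    eef_water: float = 1000.0
    eef_sediment: float = 100.0
    severity_factor: float = 0.993
    water_depth: float = 100.0
    species_density: float = 3.46e-12
    depth_for_recipe: float = 100.0

    def __post_init__(self) -> None:
        for name in ("eef_water", "eef_sediment", "severity_factor",
                     "species_density", "depth_for_recipe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.water_depth <= 0:
            raise ValueError("water_depth must be > 0")


@lru_cache(maxsize=1)
def load_canonical_cfs() -> pd.DataFrame:
    """The canonical CF dataset (45 rows, both levels), as packaged."""
    with resources.files("plastifate.data").joinpath("canonical_cfs.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def canonical_cf_lookup(polymer: str, shape: str, size: float, level: str) -> float:
    """Exact query of the canonical CF dataset.

    ``level`` is ``"midpoint"`` (PAF·m³·day/kg) or ``"endpoint"``
    (PDF·m²·yr/kg). Unknown keys raise :class:`CanonicalLookupError` listing
    the valid key space."""
    if level not in _LEVEL_COLUMN:
        raise CanonicalLookupError(
            f"level must be 'midpoint' or 'endpoint', got {level!r}")
    df = load_canonical_cfs()
    hit = df[(df["polymer"] == polymer) & (df["shape"] == shape)
             & (df["size_um"] == size)]
    if hit.empty:
        raise CanonicalLookupError(
            f"no canonical CF for ({polymer!r}, {shape!r}, {size!r}); valid "
            f"keys are {POLYMERS} x {SHAPES} x {SIZES_UM} µm")
    return float(hit[_LEVEL_COLUMN[level]].iloc[0])


def midpoint_cf(ff: FateFactors, effects: EffectParameters) -> float:
    """Midpoint CF (PAF·m³·day/kg): residence-weighted sum of the EEFs."""
    if ff.ff_water < 0 or ff.ff_sediment < 0:
        raise ValueError("fate factors must be >= 0")
    return ff.ff_water * effects.eef_water + ff.ff_sediment * effects.eef_sediment


def endpoint_cf(midpoint: float, effects: EffectParameters) -> float:
    """Endpoint CF (PDF·m²·yr/kg) = midpoint · SF / depth, with the day→yr
    conversion applied explicitly."""
    if midpoint < 0:
        raise ValueError("midpoint CF must be >= 0")
    return midpoint * effects.severity_factor / effects.water_depth / 365.0


def recipe_species_yr(endpoint: float, effects: EffectParameters | None = None) -> float:
    """Damage score (species·yr/kg emitted) from an endpoint CF."""
    if endpoint < 0:
        raise ValueError("endpoint CF must be >= 0")
    effects = effects if effects is not None else EffectParameters()
    return endpoint * effects.species_density * effects.depth_for_recipe


def _round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at the printed precision (np.round rounds
    half to even, which disagrees with reported percentages)."""
    factor = 10.0 ** ndigits
    return np.floor(abs(x) * factor + 0.5) / factor * np.sign(x)


@dataclass
class ComparativeMetrics:
    """Ratio analyses of a CF dataset (size, shape and degradability effects).

    Percentages are reductions: 100·(1 − CF_a/CF_b)."""

    size_effect_pct: pd.DataFrame       # per polymer × shape, smallest vs largest
    shape_vs_film_pct: pd.DataFrame     # per polymer × size × shape
    reduction_vs_pla_pct: pd.DataFrame  # per polymer (PCL, PBSA) × shape × size
    max_size_effect_pct: float
    max_reduction_vs_pla: dict          # polymer -> max %, over shape × size


def comparative_metrics(dataset: pd.DataFrame | None = None,
                        level: str = "midpoint") -> ComparativeMetrics:
    """Recompute the size/shape/degradability comparisons from a CF table.

    - size effect: per polymer × shape, percent difference between the
      smallest (1 µm) and largest (5000 µm) size;
    - shape effect: per polymer × size, percent by which each shape's CF is
      below the film CF of the same size;
    - degradability: per shape × size, percent reduction of PCL and PBSA CFs
      relative to the matching PLA CF, with per-polymer maxima.

    Requires a complete polymer × shape × size grid.
    """
    df = dataset if dataset is not None else load_canonical_cfs()
    col = _LEVEL_COLUMN[level]
    grid = df.set_index(["polymer", "shape", "size_um"])[col]
    expected = {(p, s, z) for p in POLYMERS for s in SHAPES for z in SIZES_UM}
    missing = expected - set(grid.index)
    if missing:
        raise ValueError(f"incomplete CF grid, missing keys: {sorted(missing)[:5]}...")

    size_rows = []
    for p in POLYMERS:
        for s in SHAPES:
            small, large = grid[(p, s, min(SIZES_UM))], grid[(p, s, max(SIZES_UM))]
            size_rows.append({
                "polymer": p, "shape": s,
                "pct_smaller": 100.0 * (1.0 - small / large),
            })
    size_df = pd.DataFrame(size_rows)

    shape_rows = []
    for p in POLYMERS:
        for z in SIZES_UM:
            film = grid[(p, "film", z)]
            for s in SHAPES:
                shape_rows.append({
                    "polymer": p, "size_um": z, "shape": s,
                    "pct_below_film": 100.0 * (1.0 - grid[(p, s, z)] / film),
                })
    shape_df = pd.DataFrame(shape_rows)

    red_rows = []
    for p in ("PCL", "PBSA"):
        for s in SHAPES:
            for z in SIZES_UM:
                red_rows.append({
                    "polymer": p, "shape": s, "size_um": z,
                    "pct_reduction_vs_pla":
                        100.0 * (1.0 - grid[(p, s, z)] / grid[("PLA", s, z)]),
                })
    red_df = pd.DataFrame(red_rows)

    return ComparativeMetrics(
        size_effect_pct=size_df,
        shape_vs_film_pct=shape_df,
        reduction_vs_pla_pct=red_df,
        max_size_effect_pct=float(size_df["pct_smaller"].max()),
        max_reduction_vs_pla={
            p: float(g["pct_reduction_vs_pla"].max())
            for p, g in red_df.groupby("polymer")
        },
    )


@dataclass
class ValidationReport:
    passed: bool
    failures: list

    def __bool__(self) -> bool:
        return self.passed


def validate_canonical_dataset(dataset: pd.DataFrame | None = None,
                               ratio_tol: float = 0.01) -> ValidationReport:
    """Check the structural regularities a physically consistent CF table
    must satisfy, naming every offending key:

    (i) CF strictly increasing with size within each polymer × shape;
    (ii) film ≥ fiber ≥ sphere at each polymer × size (surface-to-volume);
    (iii) PLA ≥ PBSA ≥ PCL at each shape × size (degradability ordering);
    (iv) endpoint/midpoint ratio constant across all rows within ±ratio_tol.
    """
    df = dataset if dataset is not None else load_canonical_cfs()
    if df.empty:
        raise ValueError("empty CF dataset")
    failures: list[str] = []
    mid = df.set_index(["polymer", "shape", "size_um"])[_LEVEL_COLUMN["midpoint"]]
    end = df.set_index(["polymer", "shape", "size_um"])[_LEVEL_COLUMN["endpoint"]]

    for p in df["polymer"].unique():
        for s in df[df["polymer"] == p]["shape"].unique():
            sizes = sorted(df[(df["polymer"] == p) & (df["shape"] == s)]["size_um"])
            for z1, z2 in zip(sizes, sizes[1:]):
                if not mid[(p, s, z1)] < mid[(p, s, z2)]:
                    failures.append(
                        f"size monotonicity: CF({p},{s},{z1}) >= CF({p},{s},{z2})")

    for p in df["polymer"].unique():
        for z in df[df["polymer"] == p]["size_um"].unique():
            try:
                film, fib, sph = (mid[(p, "film", z)], mid[(p, "fiber", z)],
                                  mid[(p, "sphere", z)])
            except KeyError:
                continue
            if not (film >= fib >= sph):
                failures.append(
                    f"shape ordering violated at ({p}, size {z}): "
                    f"film={film:g}, fiber={fib:g}, sphere={sph:g}")

    for s in df["shape"].unique():
        for z in df[df["shape"] == s]["size_um"].unique():
            try:
                pla, pbsa, pcl = (mid[("PLA", s, z)], mid[("PBSA", s, z)],
                                  mid[("PCL", s, z)])
            except KeyError:
                continue
            if not (pla >= pbsa >= pcl):
                failures.append(
                    f"degradability ordering violated at ({s}, size {z}): "
                    f"PLA={pla:g}, PBSA={pbsa:g}, PCL={pcl:g}")

    ratios = (end / mid).dropna()
    median = float(ratios.median())
    off = ratios[(ratios / median - 1.0).abs() > ratio_tol]
    for key, r in off.items():
        failures.append(
            f"endpoint/midpoint ratio {r:.4g} at {key} deviates from the "
            f"common ratio {median:.4g} by more than {ratio_tol:.0%}")

    return ValidationReport(passed=not failures, failures=failures)


def compute_cf_records(ssdr_um_per_yr: dict, fate_params, effects: EffectParameters,
                       shapes=SHAPES, sizes=SIZES_UM) -> pd.DataFrame:
    """Compute a CF table (source=computed) from per-polymer SSDRs.

    ``ssdr_um_per_yr`` maps polymer id → SSDR in µm/yr; ``fate_params`` is a
    :class:`~plastifate.fate.FateParameters` whose SSDR fields are overridden
    per polymer. Output follows the canonical schema and is never merged with
    canonical rows."""
    from dataclasses import replace
    from .fate import fate_factors
    from .ssdr import ParticleGeometry, UM_PER_YR_TO_UM_PER_DAY

    rows = []
    for polymer, vd_yr in ssdr_um_per_yr.items():
        vd_day = vd_yr * UM_PER_YR_TO_UM_PER_DAY
        params = replace(fate_params, ssdr_water=vd_day, ssdr_sediment=vd_day)
        for shape in shapes:
            for size in sizes:
                ff = fate_factors(params, ParticleGeometry(shape, size))
                mid = midpoint_cf(ff, effects)
                rows.append({
                    "polymer": polymer, "shape": shape, "size_um": size,
                    "midpoint_paf_m3_day_per_kg": mid,
                    "endpoint_pdf_m2_yr_per_kg": endpoint_cf(mid, effects),
                    "source": "computed",
                })
    return pd.DataFrame(rows)
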