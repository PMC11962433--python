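"""Scenario-based application of the CFs to a textile emission inventory.

The case study characterizes marine microplastic emissions over the life
cycle of a garment (functional unit: weekly use of one sports shirt for one
year) and compares the resulting physical-effects-on-biota (PEB) damage with
the background damage of the conventional impact categories.

Scenario grid (seven rows): emissions are either the guideline-based
plp_pfn inventory or a worst-case "high" inventory in which the end-of-life
garment fragments completely to microfibers; the CF size class is "medium"
(each record's own size), "low" (all sizes forced to 1 µm) or "high" (all
5000 µm); and the polymer CF set is the slowly degrading PLA or the fast
degrading PCL.

Background damages per impact category require a full LCI database and are an
input table here, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .characterization import (EffectParameters, load_canonical_cfs,
                               recipe_species_yr)

__all__ = [
    "ScenarioSpec", "SCENARIOS", "ImpactBreakdown",
    "apply_scenario", "contribution_analysis",
    "load_demo_inventories", "load_demo_background",
]

INVENTORY_COLUMNS = ["stage", "polymer_id", "shape", "size_um", "mass_kg",
                     "compartment"]


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario grid."""

    scenario_id: str
    emission_set: str        # {plp_pfn, high}
    cf_size_class: str       # {low, medium, high}
    polymer_cf_set: str      # {PLA, PCL}

    def __post_init__(self) -> None:
        if self.emission_set not in ("plp_pfn", "high"):
            raise ValueError(f"unknown emission set {self.emission_set!r}")
        if self.cf_size_class not in ("low", "medium", "high"):
            raise ValueError(f"unknown CF size class {self.cf_size_class!r}")
        if self.polymer_cf_set not in ("PLA", "PCL"):
            raise ValueError(f"unknown polymer CF set {self.polymer_cf_set!r}")


#: the seven scenario rows: base case, worst-case emissions, size extremes,
#: and the degradable-polymer substitutions
SCENARIOS: dict[str, ScenarioSpec] = {
    "BC": ScenarioSpec("BC", "plp_pfn", "medium", "PLA"),
    "1": ScenarioSpec("1", "high", "medium", "PLA"),
    "2.1": ScenarioSpec("2.1", "high", "low", "PLA"),
    "2.2": ScenarioSpec("2.2", "high", "high", "PLA"),
    "3.1": ScenarioSpec("3.1", "plp_pfn", "medium", "PCL"),
    "3.2": ScenarioSpec("3.2", "high", "low", "PCL"),
    "3.3": ScenarioSpec("3.3", "high", "high", "PCL"),
}

_SIZE_OVERRIDE = {"low": 1, "high": 5000}


@dataclass
class ImpactBreakdown:
    """PEB damage next to the background impact categories (species·yr/FU)."""

    peb_species_yr: float
    background_damage: pd.Series      # impact category -> species·yr
    peb_share: float                  # peb / (peb + sum(background))

    def ranked(self) -> pd.Series:
        """All categories including PEB, sorted by damage, descending."""
        full = pd.concat([
            self.background_damage,
            pd.Series({"PEB": self.peb_species_yr}),
        ])
        return full.sort_values(ascending=False)


def _validate_inventory(inventory: pd.DataFrame) -> pd.DataFrame:
    missing = set(INVENTORY_COLUMNS) - set(inventory.columns)
    if missing:
        raise ValueError(f"inventory missing columns: {sorted(missing)}")
    if (inventory["mass_kg"] < 0).any():
        bad = inventory[inventory["mass_kg"] < 0]
        raise ValueError(f"negative emission masses:\n{bad}")
    return inventory[inventory["compartment"] == "marine"]


def apply_scenario(inventory, spec: ScenarioSpec,
                   cfs: pd.DataFrame | None = None,
                   effects: EffectParameters | None = None) -> float:
    """PEB damage (species·yr per functional unit) of one scenario.

    ``inventory`` is either a single emission table or a mapping
    ``{"plp_pfn": table, "high": table}`` from which ``spec.emission_set``
    selects. Only marine-compartment records are characterized. Scenario
    substitutions (size override, polymer CF set) are applied before the CF
    lookup; each record then contributes mass × endpoint CF, converted to
    species·yr."""
    if isinstance(inventory, dict):
        if spec.emission_set not in inventory:
            raise KeyError(
                f"inventory mapping lacks emission set {spec.emission_set!r}")
        inventory = inventory[spec.emission_set]
    marine = _validate_inventory(inventory)
    if cfs is None:
        cfs = load_canonical_cfs()
    cf_index = cfs.set_index(["polymer", "shape", "size_um"])[
        "endpoint_pdf_m2_yr_per_kg"]

    total_pdf_m2_yr = 0.0
    for _, rec in marine.iterrows():
        size = _SIZE_OVERRIDE.get(spec.cf_size_class, rec["size_um"])
        key = (spec.polymer_cf_set, rec["shape"], size)
        try:
            cf = float(cf_index[key])
        except KeyError:
            raise KeyError(
                f"no CF for inventory record {rec['stage']!r} after scenario "
                f"substitution: key {key} not in the CF dataset") from None
        total_pdf_m2_yr += rec["mass_kg"] * cf
    return recipe_species_yr(total_pdf_m2_yr, effects)


def run_all_scenarios(inventories: dict, cfs: pd.DataFrame | None = None,
                      effects: EffectParameters | None = None) -> pd.Series:
    """PEB damage of every scenario in :data:`SCENARIOS` (species·yr/FU)."""
    return pd.Series({
        sid: apply_scenario(inventories, spec, cfs, effects)
        for sid, spec in SCENARIOS.items()
    })


def contribution_analysis(peb_species_yr: float,
                          background: pd.Series | dict) -> ImpactBreakdown:
    """Share of PEB in the total ecosystem damage, with a ranked table."""
    bg = pd.Series(background, dtype=float)
    if (bg < 0).any():
        raise ValueError("background damages must be >= 0")
    if peb_species_yr < 0:
        raise ValueError("PEB damage must be >= 0")
    total = peb_species_yr + bg.sum()
    if total == 0:
        raise ValueError("all-zero damage: PEB share is undefined")
    return ImpactBreakdown(
        peb_species_yr=peb_species_yr,
        background_damage=bg,
        peb_share=peb_species_yr / total,
    )


def load_demo_inventories() -> dict[str, pd.DataFrame]:
    """Synthetic demonstration inventories (guideline-based and worst-case).

    Masses are illustrative placeholders constructed for the demo, not
    measured leakage data; the worst-case set adds complete end-of-life
    fragmentation of the garment to microfibers."""
    with resources.files("plastifate.data").joinpath(
            "synthetic_demo_emission_inventory.csv").open() as fh:
        df = pd.read_csv(fh)
    return {name: grp.drop(columns="emission_set").reset_index(drop=True)
            for name, grp in df.groupby("emission_set")}


def load_demo_background() -> pd.Series:
    """Synthetic background damage table (species·yr/FU) for demonstration."""
    with resources.files("plastifate.data").joinpath(
            "synthetic_demo_background_damage.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("impact_category")["damage_species_yr"]
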