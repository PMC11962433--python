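#!/usr/bin/env python
"""Steady-state fate factors over the polymer × shape × size grid.

Converts each polymer's aggregated SSDR to first-order degradation rate
constants per geometry, combines them with the demo sedimentation /
resuspension / deep-burial rates, and solves the two-compartment model.
Writes results/fate_factors.csv (per row: rate constants and residence
times in water and sediment, in days).
"""

from dataclasses import replace
from pathlib import Path

import pandas as pd

from plastifate import (ParticleGeometry, build_rate_matrix,
                        degradation_rate_constant, steady_state_fate_factors)
from plastifate.characterization import SHAPES, SIZES_UM
from plastifate.fate import DEMO_FATE_PARAMETERS
from plastifate.ssdr import UM_PER_YR_TO_UM_PER_DAY

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rates = pd.read_csv(RESULTS / "ssdr_aggregate.csv")
    rows = []
    for _, r in rates.iterrows():
        vd_day = r["vd_um_per_yr"] * UM_PER_YR_TO_UM_PER_DAY
        params = replace(DEMO_FATE_PARAMETERS, ssdr_water=vd_day,
                         ssdr_sediment=vd_day)
        for shape in SHAPES:
            for size in SIZES_UM:
                geo = ParticleGeometry(shape, float(size))
                k_w = degradation_rate_constant(params.ssdr_water, geo)
                k_s = degradation_rate_constant(params.ssdr_sediment, geo)
                ff = steady_state_fate_factors(build_rate_matrix(params, k_w, k_s))
                rows.append({
                    "polymer": r["polymer_id"], "shape": shape, "size_um": size,
                    "k_deg_w_per_day": k_w, "k_deg_s_per_day": k_s,
                    "ff_water_days": ff.ff_water,
                    "ff_sediment_days": ff.ff_sediment,
                })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "fate_factors.csv", index=False)
    summary = df.groupby("polymer")[["ff_water_days", "ff_sediment_days"]].agg(
        ["min", "max"])
    print("fate-factor ranges per polymer (days):")
    print(summary.to_string(float_format=lambda x: f"{x:10.3g}"))
    print(f"\nwrote {RESULTS / 'fate_factors.csv'}")


if __name__ == "__main__":
    main()
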