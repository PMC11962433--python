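#!/usr/bin/env python
"""Simulate the six incubation conditions of the degradation campaign.

Generates synthetic flask-level CO2 series for powdered and granulated
polycaprolactone at 20 °C, cold (4 °C) powder, a second polymer grade, and
the slow-degrading PLA and PBSA powders. Geometry and rate settings are demo
choices that land the final degradation fractions in the observed ranges
(≈56%/58% for the two PCL powder grades, 26% granulate, 3% cold, ≈1% PLA,
3% PBSA). Writes results/incubation_series.csv.
"""

from pathlib import Path

import pandas as pd

from plastifate import SyntheticExperimentConfig, simulate_incubation

RESULTS = Path(__file__).resolve().parents[1] / "results"

# handle -> config; d0 in µm, true_ssdr in µm/yr
CONDITIONS = {
    "PCL-A_p_20": SyntheticExperimentConfig(
        polymer_id="PCL", true_ssdr=47.9, d0=200.0, c_tot=0.454, seed=101),
    "PCL-A_g_20": SyntheticExperimentConfig(
        polymer_id="PCL", true_ssdr=286.0, d0=3000.0, c_tot=0.454,
        replicate_cv=0.2, seed=102),
    "PCL-A_p_4": SyntheticExperimentConfig(
        polymer_id="PCL", true_ssdr=47.9, d0=200.0, c_tot=0.454,
        temperature_scaling=0.04, temperature_c=4.0, seed=103),
    "PCL-B_p_20": SyntheticExperimentConfig(
        polymer_id="PCL", true_ssdr=69.3, d0=276.0, c_tot=0.454,
        replicate_cv=0.4, seed=104),
    "PLA-p_20": SyntheticExperimentConfig(
        polymer_id="PLA", true_ssdr=0.87, d0=260.0, c_tot=0.493,
        replicate_cv=0.2, seed=105),
    "PBSA-p_20": SyntheticExperimentConfig(
        polymer_id="PBSA", true_ssdr=1.98, d0=196.0, c_tot=0.52,
        replicate_cv=0.2, seed=106),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    frames = []
    for handle, cfg in CONDITIONS.items():
        df = simulate_incubation(cfg)
        df.insert(0, "handle", handle)
        # prefix flask ids so conditions stay distinguishable when pooled
        df["flask_id"] = handle + ":" + df["flask_id"]
        frames.append(df)
        print(f"{handle}: {df['flask_id'].nunique()} flasks, "
              f"{df['time_days'].nunique()} time points "
              f"(true SSDR {cfg.true_ssdr * cfg.temperature_scaling:.3g} µm/yr)")
    out = RESULTS / "incubation_series.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
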