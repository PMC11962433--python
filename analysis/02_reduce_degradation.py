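#!/usr/bin/env python
"""Reduce the simulated flask CO2 series to degradation curves.

Blank-corrects each condition, normalises by the theoretical CO2 of complete
mineralisation, and summarises triplicates. Prints the final mean degradation
per condition and writes results/degradation_curves.csv.
"""

from pathlib import Path

import pandas as pd

from plastifate import build_degradation_curves

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series = pd.read_csv(RESULTS / "incubation_series.csv")
    series["polymer_id"] = series["polymer_id"].fillna("")
    frames = []
    print("final mean degradation per condition:")
    for handle, grp in series.groupby("handle"):
        curves = build_degradation_curves(grp)
        (key, curve), = curves.items()
        frame = curve.to_frame()
        frame.insert(0, "handle", handle)
        frames.append(frame)
        finals = curve.replicate_deg[:, -1]
        print(f"  {handle:12s} {curve.final():6.1%}  "
              f"(replicates {finals.min():.1%}–{finals.max():.1%})")
    out = RESULTS / "degradation_curves.csv"
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
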