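#!/usr/bin/env python
"""Classical kinematic relations: peak velocity vs amplitude, and the
inverse duration relation v*/A = c pi / T.

Reads the triples table from 02_run_pipeline.py and reports the A-v* slope
per metronome rate (expected to steepen with rate) and the dimensionless c
factor per direction (analytically bounded near one half for critically
damped gestures).  Writes results/analysis_av_slopes.csv.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import linregress

BUNDLE = Path("results/analysis")


def main():
    triples = pd.read_csv(BUNDLE / "triples.csv")
    rows = []
    for (rate, direction), grp in triples.groupby(["rate_bpm", "direction"]):
        if len(grp) < 3 or grp.A.nunique() < 2:
            continue
        fit = linregress(grp.A, grp.v_peak)
        rows.append(
            {"rate_bpm": rate, "direction": direction,
             "slope_per_s": fit.slope, "r2": fit.rvalue**2, "n": len(grp)}
        )
    slopes = pd.DataFrame(rows).sort_values(["direction", "rate_bpm"])
    slopes.to_csv("results/analysis_av_slopes.csv", index=False)

    c_table = pd.read_csv(BUNDLE / "c_factors.csv")
    print("A-v* slopes steepen with rate:")
    for direction, grp in slopes.groupby("direction"):
        print(f"  {direction}: "
              + ", ".join(f"{r.rate_bpm:g} bpm: {r.slope_per_s:.1f}/s"
                          for r in grp.itertuples()))
    print("c factors (slope of v*/A vs 1/T, in units of pi):")
    for r in c_table.itertuples():
        print(f"  {r.sequence} {r.direction}: c = {r.c:.3f} (n={r.n}, r2={r.r2:.3f})")


if __name__ == "__main__":
    main()
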