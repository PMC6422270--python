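#!/usr/bin/env python
"""Run the full conditioning-to-regression pipeline on the simulated trials.

Reads the TSV trials written by 01_simulate.py, runs decimation, head
correction, filtering, spline fitting, segmentation and all regressions, and
writes the report bundle (triples, c factors, power-law tables 3D and 2D,
phase-regime scores, summary JSON) under results/analysis.
"""

from pathlib import Path

from curvelaw.pipeline import PipelineConfig, run_pipeline

TRIALS = Path("scratch/analysis/trials")
OUT = Path("results/analysis")


def main():
    if not TRIALS.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    cfg = PipelineConfig(input_dir=str(TRIALS), output_dir=str(OUT))
    summary = run_pipeline(cfg)
    c = summary["counts"]
    print(f"movements: {c['found']} found, {c['retained']} retained "
          f"({c['closing']} closing / {c['opening']} opening)")
    print(f"speed-curvature pairs: {summary['n_speed_curvature_pairs']}")
    print(f"bundle written to {OUT}")


if __name__ == "__main__":
    main()
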