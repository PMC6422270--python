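#!/usr/bin/env python
"""Generate the synthetic metronome-rate session that all later analysis
steps consume.

Emulates the repetitive-syllable EMA paradigm: eight metronome rates from 30
to 570 bpm, two trials per rate, fifteen syllables per trial, figural
excursion shrinking from 15 to 10 mm with rate, a 7.5% lateral component,
rigid head motion on the reference sensors and additive sensor noise.  Raw
trials (large TSVs) go to scratch/analysis/trials; the ground truth JSON
sits alongside them.
"""

import sys
from pathlib import Path

from curvelaw import io as cio
from curvelaw.synthetic import SessionConfig, generate_session

OUT = Path("scratch/analysis/trials")


def main(seed: int = 1):
    cfg = SessionConfig(trials_per_rate=4, syllables_per_trial=10, seed=seed)
    recs, truth = generate_session(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    for rec in recs:
        name = (
            f"{cfg.sequence}_rate{rec.metadata['rate_bpm']:g}"
            f"_trial{rec.metadata['trial']}.tsv"
        )
        cio.write_trajectory_tsv(rec, OUT / name)
    cio.write_ground_truth(truth, OUT / "ground_truth.json")
    total = sum(r.duration for r in recs)
    print(f"wrote {len(recs)} trials ({total:.0f} s of articulation) to {OUT}")
    print(f"rates: {cfg.rates} bpm; true exponents "
          f"{cfg.beta(min(cfg.rates)):.3f} -> {cfg.beta(max(cfg.rates)):.3f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
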