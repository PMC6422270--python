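"""Plain-text interchange formats.

Trajectories travel as TSV: comment header lines ``# key: json-value``
carrying sample rate, start time, sensor roles and trial metadata, then a
column header ``t`` plus ``<sensor>_x``, ``<sensor>_y``, ``<sensor>_z`` (mm)
and one row per sample.  Ground truth is a JSON sidecar.  All floats are
written with repr-roundtrip precision so a written-and-reread recording is
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import TrajectoryRecording
from .synthetic import GroundTruth, HeadMotionSpec, SessionConfig, TrialTruth

__all__ = [
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_ground_truth",
    "read_ground_truth",
]


def write_trajectory_tsv(rec: TrajectoryRecording, path) -> None:
    path = Path(path)
    lines = [
        f"# sample_rate_hz: {json.dumps(rec.sample_rate)}",
        f"# t0: {json.dumps(rec.t0)}",
        f"# roles: {json.dumps(rec.roles, sort_keys=True)}",
        f"# metadata: {json.dumps(rec.metadata, sort_keys=True)}",
    ]
    cols = ["t"]
    data = [rec.times]
    for name in sorted(rec.channels):
        for ax, label in enumerate("xyz"):
            cols.append(f"{name}_{label}")
            data.append(rec.channels[name][:, ax])
    body = "\n".join(
        "\t".join(repr(float(v)) for v in row) for row in np.stack(data, axis=1)
    )
    path.write_text("\n".join(lines) + "\n" + "\t".join(cols) + "\n" + body + "\n")


def read_trajectory_tsv(path) -> TrajectoryRecording:
    path = Path(path)
    header: dict = {}
    n_meta = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            key, _, val = line[1:].partition(":")
            header[key.strip()] = json.loads(val.strip())
    frame = pd.read_csv(path, sep="\t", skiprows=n_meta, float_precision="round_trip")
    sensors = sorted({c[:-2] for c in frame.columns if c != "t"})
    channels = {
        s: frame[[f"{s}_x", f"{s}_y", f"{s}_z"]].to_numpy(float) for s in sensors
    }
    return TrajectoryRecording(
        sample_rate=float(header["sample_rate_hz"]),
        t0=float(header["t0"]),
        channels=channels,
        roles=header.get("roles", {}),
        metadata=header.get("metadata", {}),
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "head_motion": asdict(gt.head_motion),
        "config": {
            k: (list(v) if isinstance(v, tuple) and k == "rates" else v)
            for k, v in asdict(gt.config).items()
            if k != "head_motion"
        },
        "trials": [
            {
                "rate_bpm": tt.rate_bpm,
                "trial": tt.trial,
                "delimiters": [float(x) for x in tt.delimiters],
                "directions": tt.directions,
                "beta": tt.beta,
                "k_gain": tt.k_gain,
                "cycle_time": tt.cycle_time,
                "axis": [float(x) for x in tt.axis],
            }
            for tt in gt.trials.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    head = HeadMotionSpec(**payload["head_motion"])
    cfg_kwargs = dict(payload["config"])
    cfg_kwargs["rates"] = tuple(cfg_kwargs["rates"])
    config = SessionConfig(head_motion=head, **cfg_kwargs)
    trials = {}
    for rec in payload["trials"]:
        tt = TrialTruth(
            rate_bpm=rec["rate_bpm"],
            trial=rec["trial"],
            delimiters=np.asarray(rec["delimiters"]),
            directions=list(rec["directions"]),
            beta=rec["beta"],
            k_gain=rec["k_gain"],
            cycle_time=rec["cycle_time"],
            axis=np.asarray(rec["axis"]),
        )
        trials[(tt.rate_bpm, tt.trial)] = tt
    return GroundTruth(trials=trials, head_motion=head, config=config)
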