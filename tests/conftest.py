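"""Shared fixtures: analytic recordings and small synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from curvelaw.preprocess import TrajectoryRecording

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

RATE_EMA = 1250.0
RATE_PROC = 1250.0 / 15.0


def make_recording(t, xyz, sample_rate, sensor="tongue_tip"):
    return TrajectoryRecording(
        sample_rate=sample_rate,
        t0=float(t[0]),
        channels={sensor: np.asarray(xyz, float)},
        roles={sensor: sensor},
    )


@pytest.fixture(scope="session")
def ellipse_recording():
    """Constant-angular-velocity ellipse (a=15, b=10 mm, 2.5 Hz) at 1250 Hz.

    This parameterization satisfies v = w (ab)^(1/3) kappa^(-1/3) exactly, so
    it is the canonical one-third-law fixture.
    """
    w = 2 * np.pi * 2.5
    t = np.arange(0, 4.0, 1 / RATE_EMA)
    xyz = np.stack(
        [15 * np.cos(w * t), 10 * np.sin(w * t), np.zeros_like(t)], axis=1
    )
    return make_recording(t, xyz, RATE_EMA)


@pytest.fixture(scope="session")
def smooth_ellipse(ellipse_recording):
    from curvelaw.preprocess import decimate_two_stage
    from curvelaw.spline import fit_quintic_spline

    dec = decimate_two_stage(ellipse_recording)
    return fit_quintic_spline(dec, "tongue_tip")


@pytest.fixture(scope="session")
def small_clean_session():
    """Noise-free three-rate session with ground truth."""
    from curvelaw.synthetic import HeadMotionSpec, SessionConfig, generate_session

    cfg = SessionConfig(
        rates=(30.0, 150.0, 570.0),
        trials_per_rate=1,
        syllables_per_trial=6,
        noise_sd=0.0,
        lateral_fraction=0.0,
        head_motion=HeadMotionSpec(),
        seed=101,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_noisy_session():
    """Three-rate session at the default (realistic) study conditions."""
    from curvelaw.synthetic import SessionConfig, generate_session

    cfg = SessionConfig(
        rates=(30.0, 150.0, 570.0),
        trials_per_rate=1,
        syllables_per_trial=6,
        seed=202,
    )
    return generate_session(cfg)
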