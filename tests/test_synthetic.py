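"""Synthetic session generator: contracts, determinism, ground truth."""

import dataclasses

import numpy as np
import pytest

from curvelaw.preprocess import correct_head_and_align
from curvelaw.synthetic import (
    HeadMotionSpec,
    SessionConfig,
    bent_loop_path,
    bpm_to_hz,
    ellipse_path,
    generate_power_law_path,
    generate_session,
)

QUIET = dict(noise_sd=0.0, lateral_fraction=0.0, head_motion=HeadMotionSpec(),
             excursion_jitter=0.0)


class TestSessionContract:
    def test_one_recording_per_rate_and_trial(self):
        cfg = SessionConfig(
            rates=(30.0, 90.0, 150.0, 210.0, 300.0, 390.0, 480.0, 570.0),
            trials_per_rate=4, syllables_per_trial=1, seed=1, **QUIET,
        )
        recs, gt = generate_session(cfg)
        assert len(recs) == 32
        assert len(gt.trials) == 32
        keys = {(r.metadata["rate_bpm"], r.metadata["trial"]) for r in recs}
        assert len(keys) == 32

    def test_degenerate_settings_planar_z_zero(self):
        cfg = SessionConfig(rates=(150.0,), trials_per_rate=1,
                            syllables_per_trial=3, seed=2, **QUIET)
        recs, _ = generate_session(cfg)
        z = recs[0].channels["tongue_tip"][:, 2]
        assert np.allclose(z, z[0], atol=1e-12)

    def test_same_seed_bitwise_identical(self):
        cfg = SessionConfig(rates=(90.0, 300.0), trials_per_rate=2,
                            syllables_per_trial=2, seed=42)
        r1, g1 = generate_session(cfg)
        r2, g2 = generate_session(cfg)
        for a, b in zip(r1, r2):
            for name in a.channels:
                assert np.array_equal(a.channels[name], b.channels[name])
        for k in g1.trials:
            assert np.array_equal(g1.trials[k].delimiters, g2.trials[k].delimiters)

    def test_different_seed_differs(self):
        base = dict(rates=(90.0,), trials_per_rate=1, syllables_per_trial=2)
        r1, _ = generate_session(SessionConfig(**base, seed=1))
        r2, _ = generate_session(SessionConfig(**base, seed=2))
        assert not np.array_equal(
            r1[0].channels["tongue_tip"], r2[0].channels["tongue_tip"]
        )

    def test_negative_rate_rejected_with_value(self):
        with pytest.raises(ValueError, match="-30"):
            SessionConfig(rates=(150.0, -30.0))

    def test_excursion_decreases_with_rate(self):
        cfg = SessionConfig(rates=(30.0, 570.0), trials_per_rate=1,
                            syllables_per_trial=2, seed=3, **QUIET)
        recs, _ = generate_session(cfg)
        spans = {}
        for r in recs:
            tg = r.channels[cfg.tongue_sensor]
            c = tg - tg.mean(0)
            _, _, vt = np.linalg.svd(c, full_matrices=False)
            spans[r.metadata["rate_bpm"]] = np.ptp(c @ vt[0])
        assert spans[30.0] == pytest.approx(15.0, rel=0.01)
        assert spans[570.0] == pytest.approx(10.0, rel=0.01)

    def test_lateral_fraction_in_configured_band(self):
        cfg = SessionConfig(rates=(150.0,), trials_per_rate=1,
                            syllables_per_trial=6, noise_sd=0.0, seed=4)
        recs, _ = generate_session(cfg)
        rec = correct_head_and_align(recs[0])
        tg = rec.channels["tongue_tip"]
        c = tg - tg.mean(0)
        ratio = np.sqrt(np.mean(c[:, 2] ** 2)) / np.sqrt(
            np.mean(np.sum(c[:, :2] ** 2, axis=1))
        )
        assert 0.05 <= ratio <= 0.10

    def test_ka_sequence_uses_tongue_back(self):
        cfg = SessionConfig(rates=(150.0,), trials_per_rate=1,
                            syllables_per_trial=1, sequence="ka", seed=5)
        recs, _ = generate_session(cfg)
        assert "tongue_back" in recs[0].channels
        assert recs[0].roles["tongue_back"] == "tongue_back"


class TestGroundTruth:
    def test_delimiters_increase_and_labels_alternate(self):
        cfg = SessionConfig(rates=(90.0,), trials_per_rate=2,
                            syllables_per_trial=5, seed=6)
        _, gt = generate_session(cfg)
        for tt in gt.trials.values():
            assert np.all(np.diff(tt.delimiters) > 0)
            assert len(tt.directions) == len(tt.delimiters) - 1
            assert all(
                a != b for a, b in zip(tt.directions[:-1], tt.directions[1:])
            )
            assert len(tt.directions) == 2 * cfg.syllables_per_trial

    def test_head_transform_moves_reference_sensors(self):
        cfg = SessionConfig(rates=(150.0,), trials_per_rate=1,
                            syllables_per_trial=2, noise_sd=0.0,
                            head_motion=HeadMotionSpec(2.0, 3.0, 0.2), seed=7)
        recs, gt = generate_session(cfg)
        rec = recs[0]
        from curvelaw.synthetic import REFERENCE_SENSORS

        t = rec.times
        for i in (0, rec.n_samples // 2, rec.n_samples - 1):
            tf = gt.head_transform(t[i])
            for name, home in REFERENCE_SENSORS.items():
                assert np.allclose(
                    rec.channels[name][i], tf.apply(home[None])[0], atol=1e-9
                )

    def test_beta_and_k_monotone_in_truth(self):
        cfg = SessionConfig(trials_per_rate=1, syllables_per_trial=1, seed=8, **QUIET)
        _, gt = generate_session(cfg)
        by_rate = sorted(gt.trials.values(), key=lambda t: t.rate_bpm)
        betas = [t.beta for t in by_rate]
        ks = [t.k_gain for t in by_rate]
        assert all(a > b for a, b in zip(betas, betas[1:]))
        assert all(a < b for a, b in zip(ks, ks[1:]))


class TestPowerLawPath:
    def test_circle_constant_speed_closed_form(self):
        """On a circle of radius R the speed is k R^beta everywhere."""
        R, beta, k = 9.0, 0.5, 20.0
        rec, truth = generate_power_law_path(
            lambda u: R * ellipse_path(1.0, 1.0)(u), beta, k, n_cycles=2
        )
        pos = rec.channels["tongue_tip"]
        speeds = np.linalg.norm(np.diff(pos, axis=0), axis=1) * rec.sample_rate
        assert np.allclose(speeds, k * R**beta, rtol=1e-4)

    def test_ellipse_one_third_is_harmonic_parameterization(self):
        """beta = 1/3 on an ellipse reproduces the constant-angular-velocity
        time course x = a cos(wt), y = b sin(wt) up to phase."""
        a, b = 15.0, 10.0
        rec, truth = generate_power_law_path(
            lambda u: ellipse_path(a, b)(u), 1.0 / 3.0,
            2 * np.pi * 2.0 * (a * b) ** (1 / 3), n_cycles=2,
        )
        t = rec.times
        w = 2 * np.pi / truth["cycle_time"]
        x = rec.channels["tongue_tip"][:, 0]
        y = rec.channels["tongue_tip"][:, 1]
        phase = np.arctan2(y[0] / b, x[0] / a)
        assert np.abs(x - a * np.cos(w * t + phase)).max() < 1e-3 * a
        assert np.abs(y - b * np.sin(w * t + phase)).max() < 1e-3 * b
        assert truth["cycle_time"] == pytest.approx(0.5, rel=1e-6)

    def test_beta_zero_constant_speed_any_path(self):
        rec, _ = generate_power_law_path(bent_loop_path(), 0.0, 15.0, n_cycles=1)
        pos = rec.channels["tongue_tip"]
        speeds = np.linalg.norm(np.diff(pos, axis=0), axis=1) * rec.sample_rate
        assert np.allclose(speeds, 15.0, rtol=1e-4)

    def test_vanishing_curvature_rejected_for_positive_beta(self):
        line = lambda u: np.stack(  # noqa: E731
            [np.cos(2 * np.pi * np.asarray(u, float)), np.zeros_like(u), np.zeros_like(u)],
            axis=-1,
        )
        with pytest.raises(ValueError, match="curvature"):
            generate_power_law_path(line, 0.4, 10.0)
        # but allowed for beta = 0
        rec, _ = generate_power_law_path(line, 0.0, 10.0)
        assert rec.n_samples > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            generate_power_law_path(bent_loop_path(), -0.1, 10.0)
        with pytest.raises(ValueError, match="k_gain"):
            generate_power_law_path(bent_loop_path(), 0.3, 0.0)


class TestRoundTrip:
    def test_noise_free_law_recovery_to_permille(self):
        """fit_power_law on noise-free generator output recovers (beta, k)
        within 0.1% with r2 > 0.9999."""
        from curvelaw.powerlaw import fit_power_law, subsample_movement
        from curvelaw.segmentation import principal_motion, segment_movements
        from curvelaw.spline import fit_quintic_spline

        beta = 0.40
        path = lambda u: 7.0 * bent_loop_path()(u)  # noqa: E731  ~15 mm figure
        _, probe = generate_power_law_path(path, beta, 1.0, n_cycles=1)
        k = probe["cycle_time"] / 0.4  # one cycle per 150 bpm beat
        rec, _ = generate_power_law_path(path, beta, k, n_cycles=3)
        sm = fit_quintic_spline(rec, "tongue_tip")
        segs = segment_movements(principal_motion(sm), velocity_floor=0.001)
        samples = []
        # interior movements only: the spline domain cuts mid-movement at the
        # trace ends, so the first and last spans carry boundary error
        for i, seg in enumerate(segs[1:-1]):
            samples += subsample_movement(seg, sm, movement_id=i)
        fit = fit_power_law(
            [s.v for s in samples], [s.kappa for s in samples]
        )
        assert fit.beta == pytest.approx(beta, rel=1e-3)
        assert fit.k_gain == pytest.approx(k, rel=1e-3)
        assert fit.r2 > 0.9999


def test_metronome_conversion():
    assert bpm_to_hz(570.0) == pytest.approx(9.5)
    assert bpm_to_hz(30.0) == pytest.approx(0.5)


def test_io_roundtrip(tmp_path):
    from curvelaw import io as cio

    cfg = SessionConfig(rates=(150.0,), trials_per_rate=1,
                        syllables_per_trial=2, seed=9)
    recs, gt = generate_session(cfg)
    p = tmp_path / "trial.tsv"
    cio.write_trajectory_tsv(recs[0], p)
    back = cio.read_trajectory_tsv(p)
    assert back.sample_rate == recs[0].sample_rate
    assert back.roles == recs[0].roles
    for name in recs[0].channels:
        assert np.array_equal(back.channels[name], recs[0].channels[name])

    q = tmp_path / "truth.json"
    cio.write_ground_truth(gt, q)
    gt2 = cio.read_ground_truth(q)
    key = (150.0, 0)
    assert np.allclose(gt2.trials[key].delimiters, gt.trials[key].delimiters)
    assert gt2.trials[key].directions == gt.trials[key].directions
    assert gt2.config.seed == cfg.seed
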