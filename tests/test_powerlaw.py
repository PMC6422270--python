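"""Speed, 3D curvature, subsampling and log-log power-law estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from curvelaw.powerlaw import (
    fit_power_law,
    project_midsagittal,
    rate_direction_tables,
    samples_to_frame,
    speed_and_curvature,
    speed_and_curvature_2d,
    subsample_movement,
)
from curvelaw.segmentation import principal_motion, segment_movements
from curvelaw.spline import fit_quintic_spline
from tests.conftest import RATE_PROC, make_recording


def _smooth(t, xyz):
    return fit_quintic_spline(make_recording(t, xyz, RATE_PROC), "tongue_tip")


class TestSpeedAndCurvature:
    def test_circle_constant_curvature(self):
        """Circle radius R at angular speed w: v = R w, kappa = 1/R."""
        R, w = 12.0, 2 * np.pi * 1.5
        t = np.arange(0, 3, 1 / RATE_PROC)
        sm = _smooth(t, np.stack([R * np.cos(w * t), R * np.sin(w * t), np.zeros_like(t)], 1))
        tt = np.linspace(0.3, 2.6, 200)
        v, kappa, degen = speed_and_curvature(sm, tt)
        assert np.abs(v - R * w).max() / (R * w) < 1e-6
        assert np.abs(kappa - 1 / R).max() * R < 1e-6
        assert not degen.any()

    def test_helix_curvature_closed_form(self):
        """Helix (a cos t, a sin t, c t): kappa = a / (a^2 + c^2)."""
        a, c, w = 8.0, 3.0, 2 * np.pi
        t = np.arange(0, 3, 1 / RATE_PROC)
        sm = _smooth(
            t, np.stack([a * np.cos(w * t), a * np.sin(w * t), c * w * t], 1)
        )
        tt = np.linspace(0.3, 2.6, 200)
        _, kappa, _ = speed_and_curvature(sm, tt)
        expected = a / (a**2 + c**2)
        assert np.abs(kappa - expected).max() / expected < 1e-6

    def test_straight_line_zero_curvature_not_degenerate(self):
        t = np.arange(0, 2, 1 / RATE_PROC)
        sm = _smooth(t, np.outer(10 * t, [1.0, 0.5, 0.2]))
        tt = np.linspace(0.3, 1.7, 50)
        v, kappa, degen = speed_and_curvature(sm, tt)
        assert np.abs(kappa).max() < 1e-8
        assert not degen.any()  # speed is well above the floor

    def test_stationary_flagged_degenerate(self):
        t = np.arange(0, 2, 1 / RATE_PROC)
        xyz = np.full((t.size, 3), 4.0) + 1e-9 * np.sin(t)[:, None]
        sm = _smooth(t, xyz)
        _, _, degen = speed_and_curvature(sm, np.linspace(0.5, 1.5, 10))
        assert degen.all()

    def test_out_of_domain_rejected(self):
        t = np.arange(0, 1, 1 / RATE_PROC)
        sm = _smooth(t, np.outer(t, [1.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="domain"):
            speed_and_curvature(sm, [5.0])

    def test_parabola_vertex_curvature(self):
        """y = a x^2 traversed near the vertex: 2D kappa at the vertex = 2a."""
        a = 0.3
        t = np.arange(-1, 1, 1 / RATE_PROC)
        x = 5.0 * t
        sm = _smooth(t, np.stack([x, a * x**2, np.zeros_like(t)], 1))
        _, kappa, _ = speed_and_curvature_2d(sm, [0.0])
        assert kappa[0] == pytest.approx(2 * a, rel=1e-6)


class TestFitPowerLaw:
    def test_exact_constructed_law(self):
        kappa = np.logspace(-2, 1, 40)
        v = 30.0 * kappa**-0.4
        fit = fit_power_law(v, kappa)
        assert fit.beta == pytest.approx(0.4, abs=1e-12)
        assert fit.k_gain == pytest.approx(30.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.p < 1e-12
        assert fit.n == 40

    def test_log_base_invariance(self):
        """beta and r2 are identical under natural-log regression; k matches
        after exponentiation in the matching base."""
        rng = np.random.default_rng(1)
        kappa = np.logspace(-1.5, 0.5, 60)
        v = 20.0 * kappa**-0.35 * np.exp(rng.normal(0, 0.05, 60))
        fit = fit_power_law(v, kappa)
        res = linregress(np.log(kappa), np.log(v))
        assert fit.beta == pytest.approx(-res.slope, abs=1e-12)
        assert fit.r2 == pytest.approx(res.rvalue**2, abs=1e-12)
        assert fit.k_gain == pytest.approx(np.exp(res.intercept), rel=1e-9)

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError, match="non-degenerate"):
            fit_power_law([1.0, 2.0, 3.0], [0.1, 0.2, 0.3], [True, True, True])

    def test_pooled_strata_superposition_artifact(self):
        """Two strata with different slopes and disjoint speed ranges: the
        pooled fit has intermediate beta and lower r2 than either stratum."""
        rng = np.random.default_rng(2)
        k1 = np.logspace(-1.5, 0.5, 80)
        v1 = 8.0 * k1**-0.33 * np.exp(rng.normal(0, 0.03, 80))
        k2 = np.logspace(-1.5, 0.5, 80)
        v2 = 60.0 * k2**-0.46 * np.exp(rng.normal(0, 0.03, 80))
        f1 = fit_power_law(v1, k1)
        f2 = fit_power_law(v2, k2)
        pooled = fit_power_law(np.r_[v1, v2], np.r_[k1, k2])
        lo, hi = sorted([f1.beta, f2.beta])
        assert lo < pooled.beta < hi
        assert pooled.r2 < min(f1.r2, f2.r2)


class TestSubsample:
    def _ellipse_segments(self, smooth_ellipse):
        pm = principal_motion(smooth_ellipse)
        return segment_movements(pm)

    def test_five_interior_samples(self, smooth_ellipse):
        segs = self._ellipse_segments(smooth_ellipse)
        samples = subsample_movement(segs[2], smooth_ellipse)
        assert len(samples) == 5
        for s in samples:
            assert segs[2].t_zero_on < s.t < segs[2].t_zero_off
            assert s.v > 0
        # equidistant fractions i/6
        span = segs[2].t_zero_off - segs[2].t_zero_on
        fracs = [(s.t - segs[2].t_zero_on) / span for s in samples]
        assert np.allclose(fracs, np.arange(1, 6) / 6, atol=1e-12)

    def test_circle_arc_constant_kappa(self):
        R, w = 10.0, 2 * np.pi * 2
        t = np.arange(0, 2, 1 / RATE_PROC)
        sm = _smooth(t, np.stack([R * np.cos(w * t), R * np.sin(w * t), np.zeros_like(t)], 1))
        segs = segment_movements(principal_motion(sm))
        samples = subsample_movement(segs[1], sm)
        for s in samples:
            assert s.kappa == pytest.approx(1 / R, rel=1e-6)

    def test_sample_count_scales_with_movements(self, smooth_ellipse):
        segs = self._ellipse_segments(smooth_ellipse)
        all_samples = []
        for i, seg in enumerate(segs):
            all_samples += subsample_movement(seg, smooth_ellipse, movement_id=i)
        assert len(all_samples) == 5 * len(segs)


class TestScaleEquivariance:
    def test_spatial_scaling(self, ellipse_recording):
        """Scaling the trajectory by s multiplies v by s and kappa by 1/s;
        beta is invariant and k transforms as s^(1-beta):
        v' = s v = s k kappa^-beta = k s^(1-beta) kappa'^-beta."""
        from curvelaw.preprocess import decimate_two_stage

        s = 2.5
        scaled = ellipse_recording.map_channels(lambda a: s * a)
        sms = fit_quintic_spline(decimate_two_stage(scaled), "tongue_tip")
        smo = fit_quintic_spline(decimate_two_stage(ellipse_recording), "tongue_tip")
        tt = np.linspace(0.5, 3.5, 100)
        v0, k0, _ = speed_and_curvature(smo, tt)
        v1, k1, _ = speed_and_curvature(sms, tt)
        assert np.allclose(v1, s * v0, rtol=1e-8)
        assert np.allclose(k1, k0 / s, rtol=1e-8)

        def fits(sm):
            segs = segment_movements(principal_motion(sm))
            samp = []
            for i, seg in enumerate(segs):
                samp += subsample_movement(seg, sm, movement_id=i)
            return fit_power_law([x.v for x in samp], [x.kappa for x in samp])

        f0, f1 = fits(smo), fits(sms)
        assert f1.beta == pytest.approx(f0.beta, abs=1e-9)
        assert f1.k_gain == pytest.approx(f0.k_gain * s ** (1 - f0.beta), rel=1e-6)


class TestPlanarAndTables:
    def test_planar_2d_equals_3d(self, smooth_ellipse):
        """For z = 0 the 2D and 3D analyses agree to 1e-10."""
        tt = np.linspace(0.5, 3.5, 300)
        v3, k3, _ = speed_and_curvature(smooth_ellipse, tt)
        v2, k2, _ = speed_and_curvature_2d(smooth_ellipse, tt)
        assert np.abs(v3 - v2).max() < 1e-10
        assert np.abs(k3 - k2).max() < 1e-10

    def test_planar_session_fit_tables_identical(self, smooth_ellipse):
        segs = segment_movements(principal_motion(smooth_ellipse))
        samples = []
        for i, seg in enumerate(segs):
            for s in subsample_movement(seg, smooth_ellipse, movement_id=i):
                s.metadata.update(rate_bpm=150.0, sequence="ta", speaker="S1")
                samples.append(s)
        frame = samples_to_frame(samples)
        merged = project_midsagittal(frame)
        assert np.abs(merged["beta_3d"] - merged["beta_2d"]).max() < 1e-10
        assert np.abs(merged["r2_gain_3d"]).max() < 1e-10

    def test_lateral_component_favors_3d(self):
        """With a 5-10% lateral component the law holds along the full 3D
        trajectory, so the 3D r2 is at least the mid-sagittal 2D r2 on
        average across strata (sensor noise off to isolate the effect)."""
        from curvelaw.pipeline import PipelineConfig, process_recording
        from curvelaw.synthetic import HeadMotionSpec, SessionConfig, generate_session

        recs, _ = generate_session(
            SessionConfig(
                rates=(30.0, 150.0, 570.0), trials_per_rate=1,
                syllables_per_trial=6, noise_sd=0.0,
                head_motion=HeadMotionSpec(), seed=77,
            )
        )
        cfg = PipelineConfig()
        samples = []
        mid = 0
        for rec in recs:
            _, segs, sm = process_recording(rec, cfg)
            for seg in segs[1:-1]:
                samples += subsample_movement(seg, sm, movement_id=mid)
                mid += 1
        merged = project_midsagittal(samples_to_frame(samples))
        assert merged["r2_gain_3d"].mean() >= 0

    def test_empty_stratum_reported_na(self):
        rng = np.random.default_rng(3)
        kappa = np.logspace(-1, 0, 30)
        rows = []
        for rate in (30.0, 150.0):
            for i, k in enumerate(kappa):
                rows.append(
                    {
                        "v": 20 * k**-0.4, "kappa": k, "kappa_2d": k,
                        "degenerate": False, "movement_id": i,
                        "direction": "closing", "sequence": "ta",
                        "rate_bpm": rate,
                    }
                )
        frame = pd.DataFrame(rows)
        table = rate_direction_tables(frame, rates=[30.0, 150.0, 570.0])
        row = table[table.rate_bpm == 570.0]
        assert len(row) == 1
        assert row.n.iloc[0] == 0
        assert np.isnan(row.beta.iloc[0])
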