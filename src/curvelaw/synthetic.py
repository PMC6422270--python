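"""Synthetic EMA-like sessions with known ground truth.

This module emulates the statistical structure of a metronome-driven
repetitive-speech recording session: a tongue sensor traces a closed figural
path once per metronome beat (one closing plus one opening movement per
syllable), digitized at 1250 Hz, with

* eight metronome rates from 30 to 570 bpm and several trials per rate;
* figural excursion shrinking linearly with rate (default 15 mm at the
  slowest to 10 mm at the fastest rate);
* a speed profile constructed to satisfy the speed-curvature power law
  v = k * kappa^(-beta) exactly along the path, with a rate-dependent true
  exponent (default 0.46 at 30 bpm down to 1/3 at 570 bpm) and the gain k
  fixed by the requirement that one cycle lasts exactly one beat;
* a lateral (z) component of configurable RMS fraction (default 7.5%) of the
  in-plane displacement;
* rigid head motion carried by three reference sensors (and imparted to the
  tongue channel, as a head-mounted device would record it);
* additive i.i.d. Gaussian sensor noise per axis and sample.

Every stochastic draw flows from a single seeded generator, so identical
configurations produce bit-identical output.  The ground-truth container
records the true movement delimiters, direction labels, per-trial law
parameters and the analytic head transform for every downstream stage to be
verified against.

The default figural template is a "bent loop": an ellipse whose vertical
coordinate carries a third-harmonic bend, giving smoothly varying, strictly
positive curvature within each cycle (a pure circle would make the power-law
fit degenerate, and a curvature discontinuity would make the constructed
speed profile jump).  The bend amplitude decays with metronome rate so that
fast cycles remain band-limited, mirroring the transition from complex to
simple elliptical shapes seen at fast rates; each trial starts and ends at a
principal-axis extremum and is framed by resting pads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocess import RigidTransform, TrajectoryRecording

__all__ = [
    "HeadMotionSpec",
    "SessionConfig",
    "TrialTruth",
    "GroundTruth",
    "ellipse_path",
    "bent_loop_path",
    "generate_power_law_path",
    "generate_session",
    "generate_regime_signal",
    "bpm_to_hz",
]

#: fixed layout of the synthetic head: tongue rest position and the three
#: reference sensors (nose bridge and mastoid processes), occlusal frame, mm
TONGUE_BASE = np.array([55.0, 10.0, 0.0])
REFERENCE_SENSORS = {
    "nose_bridge": np.array([80.0, 45.0, 0.0]),
    "left_mastoid": np.array([5.0, 0.0, -55.0]),
    "right_mastoid": np.array([5.0, 0.0, 55.0]),
}
HEAD_CENTER = np.array([40.0, 20.0, 0.0])


def bpm_to_hz(bpm: float) -> float:
    """Metronome rate in beats/min to syllable-cycle frequency in Hz."""
    return bpm / 60.0


@dataclass(frozen=True)
class HeadMotionSpec:
    """Rigid head motion: sinusoidal rotation (deg) and translation (mm)."""

    rotation_deg: float = 0.0
    translation_mm: float = 0.0
    frequency_hz: float = 0.15

    @property
    def is_zero(self) -> bool:
        return self.rotation_deg == 0.0 and self.translation_mm == 0.0


@dataclass(frozen=True)
class SessionConfig:
    """Conditions of one synthetic recording session."""

    rates: tuple[float, ...] = (30.0, 90.0, 150.0, 210.0, 300.0, 390.0, 480.0, 570.0)
    syllables_per_trial: int = 30
    trials_per_rate: int = 4
    shape: str = "bent-loop"  # "bent-loop" | "ellipse"
    sequence: str = "ta"  # "ta" -> tongue_tip, "ka" -> tongue_back
    speaker: str = "S1"
    lateral_fraction: float = 0.075
    excursion_jitter: float = 0.05  # relative per-trial amplitude variability
    noise_sd: float = 0.005  # mm
    head_motion: HeadMotionSpec = HeadMotionSpec(rotation_deg=1.5, translation_mm=2.0)
    sample_rate: float = 1250.0
    excursion_slow_mm: float = 15.0
    excursion_fast_mm: float = 10.0
    beta_slow: float = 0.46
    beta_fast: float = 1.0 / 3.0
    bend_slow: float = 0.10
    shape_simplify_bpm: float = 390.0
    rest_pad_s: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for r in self.rates:
            if r <= 0:
                raise ValueError(f"metronome rate must be positive, got {r} bpm")
        if self.syllables_per_trial < 1:
            raise ValueError("syllables_per_trial must be >= 1")
        if not 0 <= self.lateral_fraction < 1:
            raise ValueError("lateral_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.sequence not in ("ta", "ka"):
            raise ValueError("sequence must be 'ta' or 'ka'")

    @property
    def tongue_sensor(self) -> str:
        return "tongue_tip" if self.sequence == "ta" else "tongue_back"

    def excursion(self, rate: float) -> float:
        """Figural excursion (mm) at a metronome rate, linear in bpm."""
        lo, hi = min(self.rates), max(self.rates)
        f = 0.0 if hi == lo else (rate - lo) / (hi - lo)
        return self.excursion_slow_mm + f * (self.excursion_fast_mm - self.excursion_slow_mm)

    def beta(self, rate: float) -> float:
        """True power-law exponent at a metronome rate, linear in bpm."""
        lo, hi = min(self.rates), max(self.rates)
        f = 0.0 if hi == lo else (rate - lo) / (hi - lo)
        return self.beta_slow + f * (self.beta_fast - self.beta_slow)

    def bend(self, rate: float) -> float:
        """Figural bend amplitude at a metronome rate.

        Decays quadratically from ``bend_slow`` at the slowest rate to zero at
        ``shape_simplify_bpm`` and beyond: movement shapes transition from a
        complex bent loop to a plain ellipse as rate increases (fast cycles
        cannot carry the bend's higher harmonics through a band-limited
        articulatory channel).
        """
        lo = min(self.rates)
        span = self.shape_simplify_bpm - lo
        if span <= 0:
            return 0.0
        return self.bend_slow * float(np.clip((self.shape_simplify_bpm - rate) / span, 0.0, 1.0)) ** 2


@dataclass
class TrialTruth:
    """Ground truth for one trial: delimiters, labels and law parameters."""

    rate_bpm: float
    trial: int
    delimiters: np.ndarray  # zero-velocity instants, s, strictly increasing
    directions: list[str]  # label of the movement starting at delimiters[i]
    beta: float
    k_gain: float
    cycle_time: float
    axis: np.ndarray  # true principal movement axis (unit 3-vector)

    def __post_init__(self):
        d = np.asarray(self.delimiters, float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("delimiters must be strictly increasing")
        for a, b in zip(self.directions[:-1], self.directions[1:]):
            if a == b:
                raise ValueError("direction labels must alternate")


@dataclass
class GroundTruth:
    """Session-level oracle: per-trial truths plus the analytic head motion."""

    trials: dict[tuple[float, int], TrialTruth]
    head_motion: HeadMotionSpec
    config: SessionConfig

    def head_transform(self, t: float) -> RigidTransform:
        return _head_transform(self.head_motion, np.atleast_1d(float(t)))[0]


# ---------------------------------------------------------------------------
# figural templates (closed curves, u in [0, 1), unit scale)


def ellipse_path(a: float = 1.0, b: float = 2.0 / 3.0):
    def path(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, float)
        return np.stack(
            [a * np.cos(2 * np.pi * u), b * np.sin(2 * np.pi * u), np.zeros_like(u)],
            axis=-1,
        )

    return path


def bent_loop_path(a: float = 1.0, b: float = 0.62, bend: float = 0.10):
    """Flattened loop with a third-harmonic bend.

    The sin(3w) term makes the two half-cycles mirror images, so closing and
    opening movements see the same within-movement curvature range (a
    second-harmonic bend would concentrate all curvature variation in one
    half, leaving the other half's power-law fit degenerate).  Curvature is
    strictly positive for bend below about 0.13 at the default flattening.
    """

    def path(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, float)
        w = 2 * np.pi * u
        return np.stack(
            [a * np.cos(w), b * (np.sin(w) + bend * np.sin(3 * w)), np.zeros_like(u)],
            axis=-1,
        )

    return path


def _path_from_shape(shape) -> "callable":
    if callable(shape):
        return shape
    if shape == "ellipse":
        return ellipse_path()
    if shape == "bent-loop":
        return bent_loop_path()
    raise ValueError(f"unknown figural template {shape!r}")


# ---------------------------------------------------------------------------
# power-law construction


def _closed_curve_geometry(path, n_fine: int):
    """Positions, speed-per-u and curvature on a fine periodic grid."""
    u = np.arange(n_fine) / n_fine
    p = path(u)
    du = 1.0 / n_fine
    d1 = (np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)) / (2 * du)
    d2 = (np.roll(p, -1, axis=0) - 2 * p + np.roll(p, 1, axis=0)) / du**2
    speed_u = np.linalg.norm(d1, axis=1)
    cross = np.cross(d1, d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.linalg.norm(cross, axis=1) / speed_u**3
    return u, p, speed_u, kappa


def generate_power_law_path(
    path,
    beta: float,
    k_gain: float,
    n_cycles: int = 1,
    sample_rate: float = 1250.0,
    phase: float = 0.0,
    n_fine: int = 8192,
    sensor: str = "tongue_tip",
    metadata: dict | None = None,
) -> tuple[TrajectoryRecording, dict]:
    """Traverse a closed path so that v = k_gain * kappa^(-beta) holds.

    The construction reparameterizes the curve by arc length:
    dt = ds / (k_gain * kappa(s)^(-beta)).  Returns the sampled recording and
    a truth dict with the cycle period.  ``phase`` shifts the starting point
    along the cycle (fraction of a cycle).
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if k_gain <= 0:
        raise ValueError("k_gain must be positive")
    path = _path_from_shape(path)
    u, p, speed_u, kappa = _closed_curve_geometry(path, n_fine)
    if beta > 0 and (
        not np.all(np.isfinite(kappa)) or kappa.min() < 1e-9 * max(kappa.max(), 1.0)
    ):
        raise ValueError(
            "path has (near-)vanishing curvature; speed would diverge for beta > 0"
        )
    v = k_gain * np.where(kappa > 0, kappa, 1.0) ** (-beta)
    dt_du = speed_u / v
    # cumulative time over one cycle at the u nodes (trapezoid, periodic)
    mid = (dt_du + np.roll(dt_du, -1)) / 2.0
    tau = np.concatenate([[0.0], np.cumsum(mid) / n_fine])
    u_nodes = np.concatenate([u, [1.0]])
    cycle_time = float(tau[-1])

    total = n_cycles * cycle_time
    t = np.arange(int(np.floor(total * sample_rate)) + 1) / sample_rate
    t_start = (phase % 1.0) * cycle_time
    t_mod = (t + t_start) % cycle_time
    u_of_t = np.interp(t_mod, tau, u_nodes)
    # periodic cubic interpolation of the positions
    spl = CubicSpline(u_nodes, np.vstack([p, p[:1]]), bc_type="periodic")
    pos = spl(u_of_t % 1.0)
    rec = TrajectoryRecording(
        sample_rate=sample_rate,
        t0=0.0,
        channels={sensor: pos},
        roles={sensor: sensor},
        metadata=metadata or {},
    )
    truth = {"beta": float(beta), "k_gain": float(k_gain), "cycle_time": cycle_time}
    return rec, truth


# ---------------------------------------------------------------------------
# head motion


def _head_transform(spec: HeadMotionSpec, t: np.ndarray) -> list[RigidTransform]:
    """Analytic rigid head motion at times ``t`` (rotation about a fixed
    oblique axis through the head center, plus sinusoidal translation)."""
    axis = np.array([1.0, 2.0, 2.0]) / 3.0
    w = 2 * np.pi * spec.frequency_hz * np.asarray(t, float)
    out = []
    for wi in w:
        ang = np.deg2rad(spec.rotation_deg) * np.sin(wi)
        k = axis
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + np.sin(ang) * kx + (1 - np.cos(ang)) * (kx @ kx)
        trans = spec.translation_mm * np.array(
            [np.sin(wi), np.sin(0.7 * wi + 1.0), np.cos(1.3 * wi)]
        )
        # rotate about the head center, then translate
        out.append(RigidTransform(rot, HEAD_CENTER - rot @ HEAD_CENTER + trans))
    return out


def _apply_head_motion(channels: dict, spec: HeadMotionSpec, t: np.ndarray) -> dict:
    if spec.is_zero:
        return channels
    tfs = _head_transform(spec, t)
    moved = {k: np.empty_like(v) for k, v in channels.items()}
    for i, tf in enumerate(tfs):
        for name, arr in channels.items():
            moved[name][i] = tf.apply(arr[i])
    return moved


# ---------------------------------------------------------------------------
# ground-truth delimiters


def _true_delimiters(clean: np.ndarray, t: np.ndarray):
    """Movement delimiters and labels of a clean (noise-free) motion window.

    The window is assumed to start and end at principal-axis extrema, so its
    endpoints are themselves delimiters.  Returns (delimiters, per-movement
    direction labels, principal axis).
    """
    from .segmentation import fix_axis_sign

    centered = clean - clean.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = fix_axis_sign(eigvecs[:, -1])
    score = centered @ axis
    vel = np.gradient(score, t)
    sign = np.sign(vel)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    zeros = t[idx] - vel[idx] * (t[idx + 1] - t[idx]) / (vel[idx + 1] - vel[idx])
    delims = np.concatenate([[t[0]], zeros, [t[-1]]])
    # guard against an interior crossing coinciding with an endpoint
    keep = np.concatenate([[True], np.diff(delims) > 2 * (t[1] - t[0])])
    delims = delims[keep]
    mids = (delims[:-1] + delims[1:]) / 2
    mid_vel = np.interp(mids, t, vel)
    directions = ["closing" if v > 0 else "opening" for v in mid_vel]
    return delims, directions, axis


# ---------------------------------------------------------------------------
# session generation


def generate_session(config: SessionConfig) -> tuple[list[TrajectoryRecording], GroundTruth]:
    """Generate one recording per (rate, trial) with full ground truth."""
    rng = np.random.default_rng(config.seed)
    path = _path_from_shape(config.shape)
    recordings: list[TrajectoryRecording] = []
    truths: dict[tuple[float, int], TrialTruth] = {}

    for rate in config.rates:
        beta = config.beta(rate)
        rate_path = (
            bent_loop_path(bend=config.bend(rate))
            if config.shape == "bent-loop"
            else path
        )
        # scale the template to the rate's excursion along its major axis,
        # and locate the extremum of the major-axis projection: each trial
        # starts and ends there (zero principal-component velocity), so a
        # trial holds exactly 2 * syllables_per_trial complete movements
        u_probe = np.arange(2048) / 2048.0
        probe = rate_path(u_probe)
        centered = probe - probe.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        extent = np.ptp(proj)
        scale = config.excursion(rate) / extent
        u_star = float(u_probe[np.argmax(proj)])
        scaled_path = lambda u, s=scale, p=rate_path: s * p(u)  # noqa: E731

        # lateral amplitude making the z RMS the configured fraction of the
        # in-plane RMS (the lateral wobble is part of the closed 3D path, so
        # the power law holds along the full 3D trajectory and a mid-sagittal
        # projection genuinely loses curvature information)
        scaled = scale * centered
        inplane_rms = np.sqrt(np.mean(np.sum(scaled[:, :2] ** 2, axis=1)))
        z_amp = config.lateral_fraction * inplane_rms * np.sqrt(2.0)

        for trial in range(config.trials_per_rate):
            meta = {
                "speaker": config.speaker,
                "sequence": config.sequence,
                "rate_bpm": rate,
                "trial": trial,
                "sensor": config.tongue_sensor,
            }
            phi = float(rng.uniform(0, 2 * np.pi)) if z_amp > 0 else 0.0
            # per-trial amplitude variability (motor variability across
            # repetitions); a pure spatial scaling, so the law is preserved
            jitter = (
                float(np.clip(1.0 + rng.normal(0.0, config.excursion_jitter), 0.5, 1.5))
                if config.excursion_jitter > 0
                else 1.0
            )

            def trial_path(u, sp=scaled_path, amp=z_amp, phi=phi, s=jitter):
                p = np.array(sp(u), float)
                if amp > 0:
                    p = p.copy()
                    p[..., 2] = amp * np.sin(2 * np.pi * np.asarray(u, float) + phi)
                return s * p

            _, probe_t = generate_power_law_path(
                trial_path, beta, 1.0, n_cycles=1,
                sample_rate=config.sample_rate, n_fine=2048,
            )
            k_gain = probe_t["cycle_time"] * bpm_to_hz(rate)
            rec, truth = generate_power_law_path(
                trial_path,
                beta,
                k_gain,
                n_cycles=config.syllables_per_trial,
                sample_rate=config.sample_rate,
                phase=u_star,
                sensor=config.tongue_sensor,
                metadata=meta,
            )
            t_motion = rec.times
            tongue = rec.channels[config.tongue_sensor]

            delims, dirs, axis = _true_delimiters(tongue, t_motion)

            # resting pads: the articulator holds position before and after
            # the syllable train (speaker listens to the metronome first)
            pad_n = int(round(config.rest_pad_s * config.sample_rate))
            if pad_n:
                tongue = np.concatenate(
                    [
                        np.repeat(tongue[:1], pad_n, axis=0),
                        tongue,
                        np.repeat(tongue[-1:], pad_n, axis=0),
                    ]
                )
                delims = delims + pad_n / config.sample_rate
            t = np.arange(tongue.shape[0]) / config.sample_rate

            clean = tongue + TONGUE_BASE
            channels = {config.tongue_sensor: clean}
            for name, pos in REFERENCE_SENSORS.items():
                channels[name] = np.broadcast_to(pos, (t.size, 3)).copy()
            channels = _apply_head_motion(channels, config.head_motion, t)
            if config.noise_sd > 0:
                for name in channels:
                    channels[name] = channels[name] + rng.normal(
                        0.0, config.noise_sd, channels[name].shape
                    )

            roles = {config.tongue_sensor: config.tongue_sensor}
            roles.update({name: "reference" for name in REFERENCE_SENSORS})
            recordings.append(
                TrajectoryRecording(
                    sample_rate=config.sample_rate,
                    t0=0.0,
                    channels=channels,
                    roles=roles,
                    metadata=meta,
                )
            )
            truths[(rate, trial)] = TrialTruth(
                rate_bpm=rate,
                trial=trial,
                delimiters=delims,
                directions=dirs,
                beta=beta,
                k_gain=k_gain,
                cycle_time=truth["cycle_time"],
                axis=axis,
            )
    return recordings, GroundTruth(trials=truths, head_motion=config.head_motion, config=config)


# ---------------------------------------------------------------------------
# control-regime signals


def generate_regime_signal(
    regime: str,
    rate_hz: float,
    duration: float,
    sample_rate: float = 1250.0,
    amplitude: float = 12.0,
    settle_factor: float = 40.0,
) -> TrajectoryRecording:
    """1D principal-axis signal embedded in 3D for the two control regimes.

    "fixed-point": concatenated critically damped gestures alternating
    between two targets, one closing+opening cycle per beat, with dwells at
    the targets (stiffness sqrt = ``settle_factor * rate_hz`` so transitions
    occupy roughly a quarter of each half-period).  "limit-cycle": sustained
    harmonic oscillation of stable amplitude.  ``duration`` must cover at
    least five cycles.
    """
    if regime not in ("fixed-point", "limit-cycle"):
        raise ValueError("regime must be 'fixed-point' or 'limit-cycle'")
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    if duration < 5.0 / rate_hz:
        raise ValueError("duration must cover at least 5 cycles")
    t = np.arange(int(duration * sample_rate) + 1) / sample_rate
    if regime == "limit-cycle":
        x = 0.5 * amplitude * np.sin(2 * np.pi * rate_hz * t)
    else:
        from .kinematics import GestureParams, gesture_closed_form

        half = 1.0 / (2.0 * rate_hz)
        omega = settle_factor * rate_hz
        x = np.empty_like(t)
        state_x, state_v = -0.5 * amplitude, 0.0
        n_half = int(np.ceil(t[-1] / half)) + 1
        for j in range(n_half):
            lo, hi = j * half, (j + 1) * half
            m = (t >= lo) & (t < hi) if j < n_half - 1 else (t >= lo)
            target = 0.5 * amplitude * (1 if j % 2 == 0 else -1)
            p = GestureParams(stiffness=omega**2, x0=state_x, v0=state_v, target=target)
            if m.any():
                x[m], _ = gesture_closed_form(p, t[m] - lo)
            state_x, state_v = (float(v[0]) for v in gesture_closed_form(p, np.array([half])))
    pos = TONGUE_BASE + np.outer(x, np.array([0.0, 1.0, 0.0]))
    return TrajectoryRecording(
        sample_rate=sample_rate,
        t0=0.0,
        channels={"tongue_tip": pos},
        roles={"tongue_tip": "tongue_tip"},
        metadata={"regime": regime, "rate_hz": rate_hz},
    )
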