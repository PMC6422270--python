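"""Signal conditioning chain for 3D articulograph trajectories.

Raw electromagnetic-articulography channels arrive at a high sampling rate
(1250 Hz by default) in a device-fixed frame.  The conditioning chain applied
before any kinematic analysis is:

1. two-stage FIR decimation (default 15x: 1250 Hz -> 83.33 Hz, two 30th-order
   equiripple lowpass stages, effective cutoff at the output Nyquist 41.67 Hz,
   group delay compensated so the chain has no net delay);
2. head-movement correction: a per-frame rigid transform estimated from the
   reference sensors by Horn's closed-form quaternion solution of the absolute
   orientation problem, followed by an optional constant occlusal-frame
   alignment;
3. zero-delay (forward-backward) Butterworth lowpass, default fourth order
   with 25 Hz cutoff.

Coordinate convention: x = anterior+, y = superior+, z = lateral+, so the
mid-sagittal plane is x-y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "TrajectoryRecording",
    "RigidTransform",
    "decimate_two_stage",
    "estimate_rigid_transform",
    "correct_head_and_align",
    "lowpass_zero_delay",
]


@dataclass
class TrajectoryRecording:
    """Uniformly sampled 3D positions (mm) of one or more sensors.

    Parameters
    ----------
    sample_rate : Hz
    t0 : time of the first sample, s
    channels : mapping sensor name -> array of shape (n_samples, 3)
    roles : mapping sensor name -> role ("tongue_tip", "tongue_back",
        "reference"); sensors without an entry are treated as auxiliary
    metadata : free-form trial metadata (speaker, sequence, rate_bpm, ...)
    """

    sample_rate: float
    t0: float
    channels: dict[str, np.ndarray]
    roles: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lengths = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr, float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"channel {name!r} must have shape (n, 3)")
            self.channels[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sample_rate

    def sensors_with_role(self, role: str) -> list[str]:
        return [s for s, r in self.roles.items() if r == role]

    def map_channels(self, fn, sample_rate=None) -> "TrajectoryRecording":
        """Apply ``fn(array) -> array`` to every channel."""
        return replace(
            self,
            sample_rate=self.sample_rate if sample_rate is None else sample_rate,
            channels={k: fn(v) for k, v in self.channels.items()},
            roles=dict(self.roles),
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R p + T (rotation matrix, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation columns not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform 'self after other'."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# decimation


def _design_stage(fs: float, factor: int, order: int) -> np.ndarray:
    """Equiripple lowpass for one decimation stage, unit DC gain.

    Band edges at 0.8x and 1.1x of the stage cutoff (the output Nyquist);
    the passband is weighted 10:1 over the stopband to keep the in-band
    ripple well below 1 percent per stage.
    """
    cutoff = fs / factor / 2.0
    taps = signal.remez(
        order + 1,
        [0.0, 0.8 * cutoff, min(1.1 * cutoff, 0.499 * fs), 0.5 * fs],
        [1.0, 0.0],
        weight=[10.0, 1.0],
        fs=fs,
    )
    return taps / taps.sum()


def _filter_zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Symmetric-FIR filtering with the group delay removed by centering."""
    half = (taps.size - 1) // 2
    pad = taps.size
    ext = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    full = np.convolve(ext, taps, mode="same")
    return full[pad : pad + x.size]


def decimate_two_stage(
    rec: TrajectoryRecording,
    factor: int = 15,
    stages: tuple[int, int] = (5, 3),
    fir_order: int = 30,
) -> TrajectoryRecording:
    """Reduce the sampling rate by ``factor`` using two FIR lowpass stages.

    Each stage is a 30th-order equiripple FIR whose cutoff sits at the stage's
    output Nyquist; the second stage therefore sets the chain's effective
    cutoff at half the final rate (41.67 Hz for 1250 -> 83.33 Hz).  Linear
    phase is compensated, so the output has no net delay.
    """
    if int(np.prod(stages)) != factor:
        a = int(round(np.sqrt(factor)))
        while factor % a:
            a -= 1
        raise ValueError(
            f"stage factors {stages} do not multiply to {factor}; "
            f"nearest valid factorization: ({factor // a}, {a})"
        )
    out = rec
    for st in stages:
        taps = _design_stage(out.sample_rate, st, fir_order)
        new_rate = out.sample_rate / st
        out = out.map_channels(
            lambda arr, taps=taps, st=st: np.stack(
                [_filter_zero_phase_fir(arr[:, ax], taps)[::st] for ax in range(3)],
                axis=1,
            ),
            sample_rate=new_rate,
        )
    return out


# ---------------------------------------------------------------------------
# rigid alignment (Horn's closed-form quaternion solution)


def estimate_rigid_transform(
    source: np.ndarray, target: np.ndarray
) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` points onto ``target``.

    Closed-form quaternion solution: the optimal rotation is the eigenvector
    of a 4x4 symmetric matrix built from the inter-set cross-covariance,
    belonging to its largest eigenvalue.  Requires at least three
    non-collinear correspondences.
    """
    s = np.asarray(source, float)
    t = np.asarray(target, float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("source and target must both have shape (n, 3)")
    if s.shape[0] < 3:
        raise ValueError("need at least 3 corresponding points")
    sc, tc = s.mean(axis=0), t.mean(axis=0)
    s0, t0 = s - sc, t - tc
    scale = max(np.linalg.norm(s0), 1e-30)
    if np.linalg.matrix_rank(s0, tol=1e-9 * scale) < 2:
        raise ValueError(
            "rank-deficient point configuration (collinear or coincident points)"
        )
    m = s0.T @ t0  # cross-covariance
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(n)
    w, x, y, z = eigvecs[:, np.argmax(eigvals)]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return RigidTransform(rot, tc - rot @ sc)


def correct_head_and_align(
    rec: TrajectoryRecording,
    reference_labels: list[str] | None = None,
    occlusal: RigidTransform | None = None,
) -> TrajectoryRecording:
    """Remove rigid head motion and align to the occlusal reference frame.

    A per-frame rigid transform is estimated from the reference sensors
    against their first-frame configuration and applied to every channel;
    reference sensors are stationary afterwards.  ``occlusal`` is an optional
    constant transform applied last (identity by default: synthetic data is
    generated directly in the occlusal frame).
    """
    if reference_labels is None:
        reference_labels = rec.sensors_with_role("reference")
    missing = [s for s in reference_labels if s not in rec.channels]
    if missing or len(reference_labels) < 3:
        raise ValueError(
            "head correction needs >= 3 reference sensors; "
            f"expected {reference_labels}, found {sorted(rec.channels)}"
        )
    refs = np.stack([rec.channels[s] for s in reference_labels], axis=1)  # (n, k, 3)
    template = refs[0]
    n = rec.n_samples
    corrected = {k: np.empty_like(v) for k, v in rec.channels.items()}
    for i in range(n):
        tf = estimate_rigid_transform(refs[i], template)
        for name, arr in rec.channels.items():
            corrected[name][i] = tf.apply(arr[i])
    if occlusal is not None:
        corrected = {k: occlusal.apply(v) for k, v in corrected.items()}
    return replace(
        rec, channels=corrected, roles=dict(rec.roles), metadata=dict(rec.metadata)
    )


# ---------------------------------------------------------------------------
# zero-delay Butterworth


def lowpass_zero_delay(
    rec: TrajectoryRecording, cutoff: float = 25.0, order: int = 4
) -> TrajectoryRecording:
    """Forward-backward Butterworth lowpass (zero net phase).

    The effective magnitude response is the squared one-pass Butterworth
    magnitude; edges are handled by reflective padding of three filter orders.
    """
    nyq = rec.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must lie below Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, fs=rec.sample_rate, output="sos")
    padlen = 3 * order

    def _apply(arr: np.ndarray) -> np.ndarray:
        return np.stack(
            [
                signal.sosfiltfilt(sos, arr[:, ax], padtype="even", padlen=padlen)
                for ax in range(3)
            ],
            axis=1,
        )

    return rec.map_channels(_apply)
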