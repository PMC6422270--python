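"""Decomposition of continuous articulator motion into closing and opening
movements.

The continuous trajectory of a tongue sensor during repetitive CV syllables is
reduced to a one-dimensional displacement along the movement direction: the
leading principal component of the trial's position samples.  Zero crossings
of the principal-component velocity are the primary movement delimiters; within
each inter-zero span, onset and offset are placed where the velocity magnitude
crosses 20% of that span's peak (earliest crossing for onset, latest for
offset, which collapses multi-peak spans into a single movement).  Direction
follows the velocity sign: closing movements (toward the palatal constriction)
have positive principal-component velocity, with the axis sign anchored to the
superior (y) coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .spline import SmoothTrajectory

__all__ = [
    "PrincipalMotion",
    "MovementSegment",
    "principal_motion",
    "segment_movements",
    "filter_targeted",
]

log = logging.getLogger(__name__)


def fix_axis_sign(axis: np.ndarray) -> np.ndarray:
    """Resolve the sign of a movement axis deterministically.

    Closing movements (toward the palatal constriction) should carry positive
    score velocity, so the axis points superior: its y component is made
    positive when substantial; for nearly horizontal axes the dominant
    component anchors the sign instead (a threshold on |y| keeps the choice
    stable under noise).
    """
    anchor = axis[1] if abs(axis[1]) >= 0.1 else axis[np.argmax(np.abs(axis))]
    return -axis if anchor < 0 else axis


@dataclass
class PrincipalMotion:
    """1D displacement of a sensor along its trial-level movement axis."""

    axis: np.ndarray  # unit 3-vector
    center: np.ndarray  # mm, trial mean position
    smooth: SmoothTrajectory
    explained_variance_fraction: float
    metadata: dict = field(default_factory=dict)

    def score(self, t) -> np.ndarray:
        """Centered displacement along the axis (mm)."""
        return (self.smooth.position(t) - self.center) @ self.axis

    def score_velocity(self, t) -> np.ndarray:
        """Velocity of the displacement score (mm/s)."""
        return self.smooth.velocity(t) @ self.axis

    @property
    def sample_times(self) -> np.ndarray:
        return self.smooth.sample_times


@dataclass
class MovementSegment:
    """One closing or opening movement with its two delimiter pairs.

    ``t_zero_on``/``t_zero_off`` are the zero-velocity delimiters,
    ``t_on``/``t_off`` the 20%-of-peak-velocity delimiters; always
    ``t_zero_on < t_on < t_off < t_zero_off``.
    """

    t_zero_on: float
    t_zero_off: float
    t_on: float
    t_off: float
    direction: str  # "closing" | "opening"
    peak_velocity_time: float
    peak_velocity: float  # mm/s, |score velocity| at the peak
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.t_zero_on < self.t_on < self.t_off < self.t_zero_off):
            raise ValueError("delimiters must satisfy t_zero_on < t_on < t_off < t_zero_off")
        if self.direction not in ("closing", "opening"):
            raise ValueError(f"unknown direction {self.direction!r}")


def principal_motion(smooth: SmoothTrajectory, oversample: int = 1) -> PrincipalMotion:
    """Leading principal component of the trial's displacement.

    The axis is the leading eigenvector of the position covariance over the
    whole trial; its sign is fixed so that motion toward the palate (superior,
    +y) gives positive score velocity during closing.
    """
    t = smooth.sample_times
    if oversample > 1:
        t = np.linspace(t[0], t[-1], t.size * oversample)
    pos = smooth.position(t)
    center = pos.mean(axis=0)
    cov = np.cov((pos - center).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    floor = 1e-18 * max(1.0, float(center @ center))
    if not np.isfinite(eigvals[-1]) or eigvals[-1] < floor:
        raise ValueError("no motion: positional variance is zero")
    axis = fix_axis_sign(eigvecs[:, -1])
    return PrincipalMotion(
        axis=axis,
        center=center,
        smooth=smooth,
        explained_variance_fraction=float(eigvals[-1] / eigvals.sum()),
        metadata=dict(smooth.metadata),
    )


def _refine_root(f, lo: float, hi: float) -> float:
    if f(lo) == 0.0:
        return lo
    if f(hi) == 0.0:
        return hi
    return brentq(f, lo, hi, xtol=1e-10)


def segment_movements(
    pm: PrincipalMotion,
    threshold: float = 0.20,
    velocity_floor: float = 1.0,
    oversample: int = 4,
) -> list[MovementSegment]:
    """Cut a trial into alternating movements delimited by velocity zeros.

    Parameters
    ----------
    threshold : onset/offset level as a fraction of the span's peak velocity.
    velocity_floor : spans whose peak |velocity| stays below this (mm/s) are
        not movements and are skipped (guards against noise micro-spans).
    oversample : dense-grid factor relative to the sampling rate used to
        bracket zero crossings before root refinement.
    """
    t0, t1 = pm.smooth.t_start, pm.smooth.t_end
    n = int(np.ceil((t1 - t0) * pm.smooth.sample_rate * oversample)) + 1
    grid = np.linspace(t0, t1, max(n, 16))
    v = pm.score_velocity(grid)

    sign = np.sign(v)
    change = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    zeros = [_refine_root(pm.score_velocity, grid[i], grid[i + 1]) for i in change]
    # samples exactly at zero
    for i in np.nonzero(sign == 0)[0]:
        zeros.append(grid[i])
    zeros = np.unique(zeros)

    segments: list[MovementSegment] = []
    for z_on, z_off in zip(zeros[:-1], zeros[1:]):
        span = grid[(grid > z_on) & (grid < z_off)]
        if span.size < 3:
            span = np.linspace(z_on, z_off, 9)[1:-1]
        vs = pm.score_velocity(span)
        direction = "closing" if np.median(vs) > 0 else "opening"
        s = 1.0 if direction == "closing" else -1.0

        # refine the peak on the signed velocity
        ipk = np.argmax(s * vs)
        lo = span[max(ipk - 1, 0)]
        hi = span[min(ipk + 1, span.size - 1)]
        res = minimize_scalar(
            lambda t: -s * pm.score_velocity(t), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        t_peak = float(res.x)
        v_peak = float(s * pm.score_velocity(t_peak))
        if v_peak < velocity_floor:
            log.debug("span [%.4f, %.4f] below velocity floor, skipped", z_on, z_off)
            continue

        level = threshold * v_peak
        g = lambda t: s * pm.score_velocity(t) - level  # noqa: E731
        above = np.nonzero(s * vs >= level)[0]
        first, last = span[above[0]], span[above[-1]]
        t_on = _refine_root(g, z_on, first) if g(z_on) < 0 else z_on + 1e-12
        t_off = _refine_root(g, last, z_off) if g(z_off) < 0 else z_off - 1e-12
        segments.append(
            MovementSegment(
                t_zero_on=float(z_on),
                t_zero_off=float(z_off),
                t_on=float(t_on),
                t_off=float(t_off),
                direction=direction,
                peak_velocity_time=t_peak,
                peak_velocity=v_peak,
                metadata=dict(pm.metadata),
            )
        )
    return segments


def filter_targeted(
    segments: list[MovementSegment],
    pm: PrincipalMotion | None = None,
    amplitude_floor_fraction: float = 0.20,
    ground_truth_delimiters: np.ndarray | None = None,
    tolerance: float = 0.05,
) -> list[MovementSegment]:
    """Drop non-targeted movements (inter-syllable drifts, rests).

    Without ground truth the rule is amplitude based: a movement whose
    principal-axis excursion is below ``amplitude_floor_fraction`` of the
    trial's reference excursion is not part of forming or releasing a
    constriction and is removed.  The reference is the median excursion of
    the movements passing a coarse screen (excursion at least
    ``amplitude_floor_fraction`` of the trial maximum): a plain median is not
    robust when noise micro-movements outnumber the targeted ones, e.g.
    during long rests at very slow rates.  With ground-truth delimiters
    available (synthetic data), a movement is kept iff its zero-velocity
    delimiters match a true movement within ``tolerance`` seconds.
    """
    if not segments:
        return []
    if ground_truth_delimiters is not None:
        gt = np.asarray(ground_truth_delimiters, float)
        kept = [
            s
            for s in segments
            if np.min(np.abs(gt - s.t_zero_on)) < tolerance
            and np.min(np.abs(gt - s.t_zero_off)) < tolerance
        ]
        return kept
    if pm is None:
        raise ValueError("need either a PrincipalMotion or ground-truth delimiters")
    excursions = []
    for s in segments:
        ts = np.linspace(s.t_zero_on, s.t_zero_off, 33)
        sc = pm.score(ts)
        excursions.append(float(sc.max() - sc.min()))
    excursions = np.asarray(excursions)
    screened = excursions[excursions >= amplitude_floor_fraction * excursions.max()]
    floor = amplitude_floor_fraction * np.median(screened)
    kept = [s for s, e in zip(segments, excursions) if e >= floor]
    if len(kept) < len(segments):
        log.info("filter_targeted removed %d of %d movements", len(segments) - len(kept), len(segments))
    return kept
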