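"""Per-movement kinematics and the mass-spring gesture model.

Every segmented movement is summarized by its kinematic triple:

* duration ``T`` -- time between the 20%-of-peak-velocity onset and offset
  delimiters (a switch allows zero-velocity delimiters instead);
* amplitude ``A`` -- 3D path length of the trajectory between the
  zero-velocity delimiters, i.e. the full figural excursion;
* peak velocity ``v*`` -- maximum tangential speed within the movement.

Two empirical relations over an ensemble of movements are fitted per stratum:
the linear peak-velocity/amplitude relation v* = c k A, and the inverse
duration relation v*/A = c pi / T whose dimensionless slope-over-pi is the
``c`` factor.  For gestures generated by a critically damped linear
oscillator, c is analytically bounded above by one half; harmonic movements
delimited at zero velocity attain exactly c = 1/2.

The standard dynamical model of a single gesture is the critically damped
harmonic oscillator  x'' = -k_s (x - target) - b x',  b = 2 sqrt(k_s),
whose closed-form solution is exposed for use as an oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .segmentation import MovementSegment
from .spline import SmoothTrajectory

__all__ = [
    "KinematicTriple",
    "CFactorFit",
    "GestureParams",
    "kinematic_triple",
    "fit_peak_velocity_amplitude",
    "fit_c_factor",
    "simulate_gesture",
    "gesture_closed_form",
]

log = logging.getLogger(__name__)


@dataclass
class KinematicTriple:
    """Duration (s), amplitude (mm, 3D path length) and peak speed (mm/s)."""

    T: float
    A: float
    v_peak: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("movement duration must be positive")
        if self.A <= 0:
            raise ValueError("movement amplitude must be positive")


@dataclass
class CFactorFit:
    """No-intercept regression of v*/A on 1/T; ``c`` is the slope in units of pi."""

    c: float
    n: int
    r2: float
    stratum: tuple = ()


@dataclass
class GestureParams:
    """Parameters of the damped linear oscillator gesture model.

    ``stiffness`` k_s (1/s^2) is the control parameter; critical damping
    fixes the damping constant b = 2 sqrt(k_s) (damping ratio 1).
    """

    stiffness: float
    x0: float
    v0: float = 0.0
    target: float = 0.0
    damping_ratio: float = 1.0

    @property
    def omega(self) -> float:
        return float(np.sqrt(self.stiffness))

    @property
    def damping(self) -> float:
        return 2.0 * self.damping_ratio * self.omega


def _arc_length(smooth: SmoothTrajectory, t0: float, t1: float, oversample: int = 8) -> float:
    """Path length of the 3D trajectory over [t0, t1] by composite Simpson."""
    from scipy.integrate import simpson

    n = max(int(np.ceil((t1 - t0) * smooth.sample_rate * oversample)), 8)
    n += n % 2  # even interval count
    ts = np.linspace(t0, t1, n + 1)
    return float(simpson(smooth.speed(ts), x=ts))


def kinematic_triple(
    seg: MovementSegment,
    smooth: SmoothTrajectory,
    amplitude_delimiters: str = "zero",
    duration_delimiters: str = "threshold",
) -> KinematicTriple:
    """Compute (T, A, v*) for one movement.

    ``amplitude_delimiters`` / ``duration_delimiters`` select "zero"
    (zero-velocity) or "threshold" (20% peak velocity) delimiters for the
    respective quantity; the defaults use the 20% window for duration and the
    full zero-to-zero path for amplitude, so A equals the figural excursion.
    Peak speed is the maximum tangential (3D) speed over the zero-to-zero
    window, refined by bounded scalar optimization.
    """
    for name, val in (("amplitude", amplitude_delimiters), ("duration", duration_delimiters)):
        if val not in ("zero", "threshold"):
            raise ValueError(f"{name}_delimiters must be 'zero' or 'threshold'")
    ta, tb = (
        (seg.t_zero_on, seg.t_zero_off)
        if amplitude_delimiters == "zero"
        else (seg.t_on, seg.t_off)
    )
    td0, td1 = (
        (seg.t_on, seg.t_off)
        if duration_delimiters == "threshold"
        else (seg.t_zero_on, seg.t_zero_off)
    )
    T = td1 - td0
    if T <= 0:
        raise ValueError("degenerate segment: non-positive duration")
    A = _arc_length(smooth, ta, tb)

    lo, hi = seg.t_zero_on, seg.t_zero_off
    ts = np.linspace(lo, hi, 129)
    speeds = smooth.speed(ts)
    i = int(np.argmax(speeds))
    res = minimize_scalar(
        lambda t: -smooth.speed(t),
        bounds=(ts[max(i - 1, 0)], ts[min(i + 1, ts.size - 1)]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    v_peak = float(max(-res.fun, speeds[i]))
    return KinematicTriple(T=float(T), A=A, v_peak=v_peak, metadata=dict(seg.metadata))


def fit_peak_velocity_amplitude(triples: list[KinematicTriple]):
    """Ordinary least squares of v* on A for one stratum.

    Returns (slope 1/s, intercept mm/s, r2) or None when the stratum is too
    small or amplitude has no variance.
    """
    if len(triples) < 3:
        log.info("A-v* stratum skipped: n=%d < 3", len(triples))
        return None
    a = np.array([t.A for t in triples])
    v = np.array([t.v_peak for t in triples])
    if np.ptp(a) == 0:
        log.info("A-v* stratum skipped: zero amplitude variance")
        return None
    fit = linregress(a, v)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def fit_c_factor(triples: list[KinematicTriple], stratum: tuple = ()) -> CFactorFit:
    """No-intercept least squares of v*/A on 1/T; c = slope / pi.

    The model v*/A = c pi / T has no additive constant, hence the regression
    is through the origin and r2 is the uncentered coefficient of
    determination.
    """
    if len(triples) < 3:
        raise ValueError(f"c-factor fit needs n >= 3 triples, got {len(triples)}")
    x = np.array([1.0 / t.T for t in triples])
    y = np.array([t.v_peak / t.A for t in triples])
    slope = float(x @ y / (x @ x))
    resid = y - slope * x
    r2 = float(1.0 - (resid @ resid) / (y @ y))
    return CFactorFit(c=slope / np.pi, n=len(triples), r2=r2, stratum=stratum)


# ---------------------------------------------------------------------------
# gesture model


def gesture_closed_form(p: GestureParams, t: np.ndarray):
    """Closed-form displacement and velocity of the critically damped gesture.

    x(t) = target + (dx0 + (v0 + w dx0) t) exp(-w t), with w = sqrt(k_s) and
    dx0 = x0 - target.  Only valid for damping ratio 1.
    """
    if p.damping_ratio != 1.0:
        raise ValueError("closed form implemented for critical damping only")
    t = np.asarray(t, float)
    w = p.omega
    dx0 = p.x0 - p.target
    e = np.exp(-w * t)
    x = p.target + (dx0 + (p.v0 + w * dx0) * t) * e
    v = (p.v0 - w * (p.v0 + w * dx0) * t) * e
    return x, v


def simulate_gesture(p: GestureParams, dt: float, duration: float):
    """Numerically integrate the gesture dynamics; returns (t, x, v).

    A non-critical damping ratio is accepted (the general damped oscillator)
    but flagged with a warning as being outside the standard gesture model.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    if p.damping_ratio != 1.0:
        warnings.warn(
            "damping ratio != 1: outside the standard (critically damped) gesture model",
            stacklevel=2,
        )
    t = np.arange(0.0, duration + 0.5 * dt, dt)

    def rhs(_, y):
        x, v = y
        return [v, -p.stiffness * (x - p.target) - p.damping * v]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [p.x0, p.v0],
        t_eval=t,
        method="DOP853",
        rtol=1e-11,
        atol=1e-12,
    )
    return t, sol.y[0], sol.y[1]
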