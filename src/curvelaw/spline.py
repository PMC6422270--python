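"""Analytic signal representation: penalized quintic regression splines and
high-order stencil differentiation.

Articulator kinematics (position, velocity, acceleration and jerk) are needed
simultaneously and consistently: curvature estimation divides by the cube of
speed and multiplies first and second derivatives, so independent smoothing of
each quantity would introduce inconsistencies.  Two differentiators are
provided:

* :class:`SmoothTrajectory` -- a per-axis quintic B-spline fitted by penalized
  least squares with one knot per sample, yielding a single analytic object
  that returns derivatives 0..3 anywhere in its domain;
* :func:`nine_point_derivative` -- nine-point finite-difference stencils of
  eighth order of accuracy applied directly to uniformly sampled series.

The quintic least-squares problem with a knot at every sample is rank deficient
by the spline space's extra degrees of freedom; a small roughness penalty on
the jumps of the fifth derivative across the interior knots selects a unique
solution.  This penalty's null space is exactly the global quintic
polynomials, so data sampled from a quintic is reproduced with exact
derivatives at every order, while the oscillatory modes that vanish at the
sample points (the source of the rank deficiency) carry large fifth-derivative
jumps and are suppressed.  The penalty weight is relative to the design
matrix's own scale, so the default behaves identically for signals in
micrometres or metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.sparse.linalg import spsolve

__all__ = [
    "SmoothTrajectory",
    "fit_quintic_spline",
    "fit_quintic_axis",
    "nine_point_derivative",
    "stencil_coefficients",
]

_DEGREE = 5


def _knot_vector(x: np.ndarray) -> np.ndarray:
    """Clamped knot vector with an interior knot at every sample instant."""
    return np.concatenate(
        [np.full(_DEGREE + 1, x[0]), x[1:-1], np.full(_DEGREE + 1, x[-1])]
    )


def _fifth_derivative_operator(knots: np.ndarray, ncoef: int) -> sparse.csr_matrix:
    """Sparse operator mapping quintic B-spline coefficients to the
    piecewise-constant fifth derivative, one value per knot interval."""
    op = sparse.eye(ncoef, format="csr")
    t = knots
    for k in range(_DEGREE, 0, -1):
        m = op.shape[0]
        span = t[k + 1 : k + m] - t[1:m]
        diff = sparse.diags([-1.0, 1.0], [0, 1], shape=(m - 1, m)).tocsr()
        op = sparse.diags(k / span) @ diff @ op
        t = t[1:-1]
    return op


def fit_quintic_axis(
    t: np.ndarray, y: np.ndarray, smooth: float = 1e-3
) -> BSpline:
    """Fit one scalar channel with a penalized quintic regression spline.

    Parameters
    ----------
    t : uniformly increasing sample instants (s).
    y : channel values at ``t``.
    smooth : relative weight of the fifth-derivative jump penalty.  The
        absolute weight is scaled by ``trace(B'B)/trace(P'P)`` so the value is
        dimensionless.

    Returns
    -------
    scipy.interpolate.BSpline of degree 5, C4-continuous at the knots (which
    implies the required C3 continuity).
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    if n < 2 * (_DEGREE + 1):
        raise ValueError(
            f"quintic spline fit needs at least {2 * (_DEGREE + 1)} samples, got {n}"
        )
    knots = _knot_vector(t)
    design = BSpline.design_matrix(t, knots, _DEGREE)  # (n, n+4) sparse CSR
    ncoef = design.shape[1]
    # build the penalty on affinely rescaled (unit-spacing) knots: B-spline
    # coefficients are invariant under affine knot maps, and the rescaling
    # keeps the normal matrix well conditioned
    h = (t[-1] - t[0]) / (n - 1)
    d5 = _fifth_derivative_operator(_knot_vector(t / h), ncoef)
    jumps = sparse.diags([-1.0, 1.0], [0, 1], shape=(d5.shape[0] - 1, d5.shape[0])) @ d5
    btb = (design.T @ design).tocsc()
    ptp = (jumps.T @ jumps).tocsc()
    lam = smooth * (btb.diagonal().sum() / max(ptp.diagonal().sum(), 1e-300))
    coef = spsolve(btb + lam * ptp, design.T @ y)
    return BSpline(knots, coef, _DEGREE, extrapolate=False)


@dataclass
class SmoothTrajectory:
    """Analytic quintic-spline representation of one sensor's 3D trajectory.

    Houses x, y, z and their first three derivatives in a single object;
    evaluation outside ``[t_start, t_end]`` raises.
    """

    splines: tuple[BSpline, BSpline, BSpline]
    t_start: float
    t_end: float
    sample_rate: float
    sample_times: np.ndarray = field(repr=False)
    metadata: dict = field(default_factory=dict)

    def _check_domain(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        if np.any(t < self.t_start - 1e-12) or np.any(t > self.t_end + 1e-12):
            raise ValueError(
                f"evaluation time outside spline domain [{self.t_start}, {self.t_end}]"
            )
        return np.clip(t, self.t_start, self.t_end)

    def evaluate(self, t, deriv: int = 0) -> np.ndarray:
        """Return positions (mm) or derivatives (mm/s^deriv), shape (..., 3)."""
        if not 0 <= deriv <= 3:
            raise ValueError("derivative order must be 0..3")
        t = self._check_domain(t)
        return np.stack([s(t, nu=deriv) for s in self.splines], axis=-1)

    def position(self, t) -> np.ndarray:
        return self.evaluate(t, 0)

    def velocity(self, t) -> np.ndarray:
        return self.evaluate(t, 1)

    def acceleration(self, t) -> np.ndarray:
        return self.evaluate(t, 2)

    def speed(self, t) -> np.ndarray:
        return np.linalg.norm(self.velocity(t), axis=-1)


def fit_quintic_spline(rec, sensor: str | None = None, smooth: float = 1e-3):
    """Fit :class:`SmoothTrajectory` objects to a trajectory recording.

    ``rec`` is a :class:`curvelaw.preprocess.TrajectoryRecording`.  With
    ``sensor`` given, returns a single SmoothTrajectory; otherwise a dict over
    all sensors.
    """
    t = rec.times
    if sensor is not None:
        data = rec.channels[sensor]
        spl = tuple(fit_quintic_axis(t, data[:, ax], smooth) for ax in range(3))
        return SmoothTrajectory(
            spl, float(t[0]), float(t[-1]), rec.sample_rate, t,
            {**rec.metadata, "sensor": sensor},
        )
    return {name: fit_quintic_spline(rec, name, smooth) for name in rec.channels}


# ---------------------------------------------------------------------------
# nine-point finite differences


def _solve_rational(a: list[list[Fraction]], b: list[Fraction]) -> list[Fraction]:
    """Gaussian elimination over exact rationals (tiny systems only)."""
    n = len(b)
    m = [row[:] + [b[i]] for i, row in enumerate(a)]
    for col in range(n):
        piv = next(r for r in range(col, n) if m[r][col] != 0)
        m[col], m[piv] = m[piv], m[col]
        inv = Fraction(1) / m[col][col]
        m[col] = [v * inv for v in m[col]]
        for r in range(n):
            if r != col and m[r][col] != 0:
                f = m[r][col]
                m[r] = [vr - f * vc for vr, vc in zip(m[r], m[col])]
    return [m[r][n] for r in range(n)]


@lru_cache(maxsize=None)
def stencil_coefficients(offsets: tuple[int, ...], deriv_order: int) -> tuple:
    """Finite-difference weights (for unit spacing) on integer ``offsets``.

    Exact rational solve of the Vandermonde moment conditions: the returned
    stencil differentiates polynomials up to degree ``len(offsets)-1`` exactly.
    """
    n = len(offsets)
    if deriv_order >= n:
        raise ValueError("derivative order must be below the stencil size")
    a = [[Fraction(o) ** i for o in offsets] for i in range(n)]
    b = [Fraction(0)] * n
    b[deriv_order] = Fraction(math.factorial(deriv_order))
    return tuple(_solve_rational(a, b))


def nine_point_derivative(
    series: np.ndarray, h: float, deriv_order: int = 1
) -> np.ndarray:
    """Differentiate a uniformly sampled series with nine-point stencils.

    Interior points use the symmetric stencil (eighth order of accuracy);
    points within four samples of either boundary use shifted nine-point
    stencils that remain exact for polynomials up to degree eight.  Output
    length equals input length.  ``deriv_order`` is 1 or 2.
    """
    y = np.asarray(series, float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if y.size < 9:
        raise ValueError(f"nine-point stencil needs at least 9 samples, got {y.size}")
    if h <= 0:
        raise ValueError("step h must be positive")
    if deriv_order not in (1, 2):
        raise ValueError("deriv_order must be 1 or 2")

    out = np.empty_like(y)
    scale = h**deriv_order
    central = np.array(
        stencil_coefficients(tuple(range(-4, 5)), deriv_order), float
    )
    out[4:-4] = np.convolve(y, central[::-1], mode="valid") / scale
    for i in range(4):
        left = np.array(
            stencil_coefficients(tuple(range(-i, 9 - i)), deriv_order), float
        )
        out[i] = left @ y[:9] / scale
        right = np.array(
            stencil_coefficients(tuple(range(-(8 - i), i + 1)), deriv_order), float
        )
        out[y.size - 1 - i] = right @ y[-9:] / scale
    return out
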