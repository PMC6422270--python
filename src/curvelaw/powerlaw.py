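"""Speed-curvature power-law estimation in three dimensions.

The power law  v = k * kappa^(-beta)  relates instantaneous tangential speed
v = |r'| to the local curvature of the effector's 3D trajectory,

    kappa = |r' x r''| / |r'|^3 ,

computed here via the cross product of the spline-consistent first and second
derivatives.  Taking logarithms turns the law into the straight line
log v = log k - beta log kappa, fitted by ordinary least squares; base 10 is
used for reporting so the velocity gain factor k carries its conventional
magnitude.  Each movement contributes five strictly interior, equal-time
subsamples between its zero-velocity delimiters (interior placement keeps
v > 0 so the logarithm is defined).  Samples whose speed falls below a floor
are flagged degenerate -- the cross product of nearly linearly dependent
derivative vectors is dominated by rounding -- and excluded from regressions
but never silently dropped from the sample table.

No curvature-range exclusion is applied anywhere: once the analysis is
three-dimensional and rate-stratified, extremal curvature values need no
special treatment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .segmentation import MovementSegment
from .spline import SmoothTrajectory

__all__ = [
    "SpeedCurvatureSample",
    "PowerLawFit",
    "speed_and_curvature",
    "speed_and_curvature_2d",
    "subsample_movement",
    "samples_to_frame",
    "fit_power_law",
    "rate_direction_tables",
    "project_midsagittal",
]

log = logging.getLogger(__name__)

SPEED_FLOOR = 1e-3  # mm/s; below this the curvature estimate is degenerate


@dataclass
class SpeedCurvatureSample:
    """One (v, kappa) pair drawn from a movement, with stratification labels."""

    t: float
    v: float  # mm/s
    kappa: float  # 1/mm
    kappa_2d: float  # mid-sagittal (x-y) curvature at the same instant
    degenerate: bool
    movement_id: int
    direction: str
    metadata: dict = field(default_factory=dict)


@dataclass
class PowerLawFit:
    """Log-log OLS result: v = k * kappa^(-beta)."""

    beta: float
    log_k: float  # log10 of the velocity gain factor
    r2: float
    p: float
    n: int
    stratum: tuple = ()

    @property
    def k_gain(self) -> float:
        return float(10.0**self.log_k)


def speed_and_curvature(smooth: SmoothTrajectory, t, speed_floor: float = SPEED_FLOOR):
    """Tangential speed and 3D curvature at times ``t``.

    Returns (v, kappa, degenerate_mask).  kappa = |r' x r''| / |r'|^3; where
    the speed is below ``speed_floor`` the estimate is flagged degenerate
    (and kappa is reported as computed, possibly huge or nan).
    """
    r1 = smooth.velocity(t)
    r2 = smooth.acceleration(t)
    v = np.linalg.norm(r1, axis=-1)
    cross = np.cross(r1, r2)
    degenerate = v < speed_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.linalg.norm(cross, axis=-1) / v**3
    return v, kappa, degenerate


def speed_and_curvature_2d(smooth: SmoothTrajectory, t, speed_floor: float = SPEED_FLOOR):
    """Planar speed and curvature of the mid-sagittal (x-y) projection."""
    r1 = smooth.velocity(t)[..., :2]
    r2 = smooth.acceleration(t)[..., :2]
    v = np.linalg.norm(r1, axis=-1)
    num = np.abs(r1[..., 0] * r2[..., 1] - r2[..., 0] * r1[..., 1])
    degenerate = v < speed_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = num / v**3
    return v, kappa, degenerate


def subsample_movement(
    seg: MovementSegment,
    smooth: SmoothTrajectory,
    n: int = 5,
    movement_id: int = 0,
    spacing: str = "time",
) -> list[SpeedCurvatureSample]:
    """Draw ``n`` equidistant samples from a movement's zero-to-zero window.

    Sample times sit at the strictly interior fractions i/(n+1),
    i = 1..n, of [t_zero_on, t_zero_off] (equidistant in time; ``spacing``
    "arclength" instead spaces them equally along the path).  Endpoints are
    excluded because the speed vanishes there.
    """
    if spacing not in ("time", "arclength"):
        raise ValueError("spacing must be 'time' or 'arclength'")
    dt = seg.t_zero_off - seg.t_zero_on
    fracs = np.arange(1, n + 1) / (n + 1)
    if spacing == "time":
        times = seg.t_zero_on + fracs * dt
    else:
        dense = np.linspace(seg.t_zero_on, seg.t_zero_off, 257)
        sp = smooth.speed(dense)
        s = np.concatenate([[0.0], np.cumsum((sp[1:] + sp[:-1]) / 2 * np.diff(dense))])
        times = np.interp(fracs * s[-1], s, dense)
    v, kappa, degen = speed_and_curvature(smooth, times)
    _, kappa2d, _ = speed_and_curvature_2d(smooth, times)
    return [
        SpeedCurvatureSample(
            t=float(times[i]),
            v=float(v[i]),
            kappa=float(kappa[i]),
            kappa_2d=float(kappa2d[i]),
            degenerate=bool(degen[i]),
            movement_id=movement_id,
            direction=seg.direction,
            metadata=dict(seg.metadata),
        )
        for i in range(n)
    ]


def samples_to_frame(samples: list[SpeedCurvatureSample]) -> pd.DataFrame:
    """Tidy table of samples with stratification columns pulled from metadata."""
    rows = []
    for s in samples:
        row = {
            "t": s.t,
            "v": s.v,
            "kappa": s.kappa,
            "kappa_2d": s.kappa_2d,
            "degenerate": s.degenerate,
            "movement_id": s.movement_id,
            "direction": s.direction,
        }
        for key in ("rate_bpm", "sequence", "speaker", "sensor", "trial"):
            if key in s.metadata:
                row[key] = s.metadata[key]
        rows.append(row)
    return pd.DataFrame(rows)


def fit_power_law(
    v: np.ndarray,
    kappa: np.ndarray,
    degenerate: np.ndarray | None = None,
    stratum: tuple = (),
) -> PowerLawFit:
    """OLS of log10 v on log10 kappa; beta = -slope, k from the intercept.

    ``p`` is the two-sided significance of the Pearson correlation.  Beta and
    r2 are invariant under the choice of logarithm base.
    """
    v = np.asarray(v, float)
    kappa = np.asarray(kappa, float)
    keep = np.isfinite(v) & np.isfinite(kappa) & (v > 0) & (kappa > 0)
    if degenerate is not None:
        keep &= ~np.asarray(degenerate, bool)
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"power-law fit needs >= 3 non-degenerate samples, got {n}")
    res = linregress(np.log10(kappa[keep]), np.log10(v[keep]))
    return PowerLawFit(
        beta=float(-res.slope),
        log_k=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=n,
        stratum=stratum,
    )


def fit_power_law_samples(samples: list[SpeedCurvatureSample], stratum: tuple = (), planar: bool = False) -> PowerLawFit:
    v = np.array([s.v for s in samples])
    kappa = np.array([s.kappa_2d if planar else s.kappa for s in samples])
    degen = np.array([s.degenerate for s in samples])
    return fit_power_law(v, kappa, degen, stratum=stratum)


def rate_direction_tables(
    samples: pd.DataFrame,
    by: tuple[str, ...] = ("sequence", "direction", "rate_bpm"),
    planar: bool = False,
    rates: list | None = None,
) -> pd.DataFrame:
    """One power-law fit per stratum; empty strata appear as NaN ('n/a') rows.

    ``samples`` is the tidy frame from :func:`samples_to_frame`.  ``rates``
    optionally forces rows for rates without data so the output table layout
    is complete.
    """
    kcol = "kappa_2d" if planar else "kappa"
    rows = []
    groups = dict(tuple(samples.groupby(list(by), sort=True)))
    keys = list(groups)
    if rates is not None and "rate_bpm" in by:
        idx = by.index("rate_bpm")
        seen = {k[: idx] + k[idx + 1 :] for k in keys}
        for base in seen:
            for r in rates:
                key = base[:idx] + (r,) + base[idx:]
                if key not in groups:
                    keys.append(key)
    for key in sorted(keys, key=str):
        grp = groups.get(key)
        rec = dict(zip(by, key))
        if grp is None or (~grp["degenerate"] & (grp[kcol] > 0)).sum() < 3:
            rec.update(beta=np.nan, log_k=np.nan, k_gain=np.nan, r2=np.nan, p=np.nan, n=0)
        else:
            fit = fit_power_law(grp["v"], grp[kcol], grp["degenerate"], stratum=key)
            rec.update(
                beta=fit.beta, log_k=fit.log_k, k_gain=fit.k_gain,
                r2=fit.r2, p=fit.p, n=fit.n,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def project_midsagittal(samples: pd.DataFrame, by: tuple[str, ...] = ("sequence", "direction", "rate_bpm"), rates: list | None = None) -> pd.DataFrame:
    """Paired 2D (mid-sagittal) vs 3D power-law comparison per stratum.

    The same subsample instants are reused; the returned table carries both
    fits and the r2 difference (3D minus 2D) per stratum.
    """
    t3 = rate_direction_tables(samples, by=by, planar=False, rates=rates)
    t2 = rate_direction_tables(samples, by=by, planar=True, rates=rates)
    merged = t3.merge(t2, on=list(by), suffixes=("_3d", "_2d"))
    merged["r2_gain_3d"] = merged["r2_3d"] - merged["r2_2d"]
    return merged
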