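"""Phase-portrait density approximations and regime scoring.

A second-order control regime leaves a signature in the (x, x') plane of the
principal-component signal: trajectories governed by fixed-point dynamics
dwell near their targets, piling occupancy mass into localized point-like
blobs, while a limit-cycle regime sweeps a closed orbit, spreading mass along
a ring.  ``phase_density`` builds a normalized occupancy-time histogram of
the phase trajectory (optionally kernel-smoothed); ``regime_score`` reduces
the density to a scalar in [0, 1] separating the two topologies.

Scoring rule (a deliberate quantitative extension of what is otherwise a
visual classification; the threshold is configuration, not a claim):
threshold the smoothed density at a fraction of its maximum, fill the
enclosed holes of the resulting high-occupancy set, and compare areas.  A
ring encloses a hole, so filling inflates its area and the score
area(set)/area(filled set) drops toward 0; point-like blobs have no holes and
score near 1.  Scores above 0.5 are read as point-like / fixed-point,
below as ring-like / limit-cycle; a high-occupancy set covering almost the
whole grid (e.g. uniform density) is reported as indeterminate with score 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import PrincipalMotion

__all__ = ["PhaseDensity", "phase_density", "regime_score"]


@dataclass
class PhaseDensity:
    """Normalized occupancy density over a (score, score-velocity) grid."""

    x_edges: np.ndarray  # mm
    v_edges: np.ndarray  # mm/s
    density: np.ndarray  # shape (nx, nv), sums to 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")
        total = self.density.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"density must sum to 1, got {total}")


def phase_density(
    pm: PrincipalMotion,
    bins: int | tuple[int, int] = 100,
    percentile_box: tuple[float, float] = (1.0, 99.0),
    smoothing_cells: float = 1.0,
    oversample: int = 4,
) -> PhaseDensity:
    """Occupancy-time histogram of the (x, x') phase trajectory.

    The grid covers the ``percentile_box`` bounding box of the data (samples
    outside it are clipped onto the edge cells so occupancy time is
    conserved), with optional Gaussian kernel smoothing measured in cells.
    """
    t = pm.sample_times
    if t.size == 0:
        raise ValueError("empty signal")
    if oversample > 1:
        t = np.linspace(t[0], t[-1], t.size * oversample)
    x = pm.score(t)
    v = pm.score_velocity(t)
    lo_p, hi_p = percentile_box
    x_lo, x_hi = np.percentile(x, [lo_p, hi_p])
    v_lo, v_hi = np.percentile(v, [lo_p, hi_p])
    if x_hi <= x_lo:
        x_lo, x_hi = x_lo - 0.5, x_lo + 0.5
    if v_hi <= v_lo:
        v_lo, v_hi = v_lo - 0.5, v_lo + 0.5
    if isinstance(bins, int):
        bins = (bins, bins)
    hist, x_edges, v_edges = np.histogram2d(
        np.clip(x, x_lo, x_hi),
        np.clip(v, v_lo, v_hi),
        bins=bins,
        range=[[x_lo, x_hi], [v_lo, v_hi]],
    )
    if smoothing_cells > 0:
        hist = ndimage.gaussian_filter(hist, sigma=smoothing_cells, mode="constant")
    hist = hist / hist.sum()
    return PhaseDensity(x_edges, v_edges, hist, metadata=dict(pm.metadata))


def regime_score(
    pd_: PhaseDensity,
    level: float = 0.2,
    cover_limit: float = 0.9,
) -> tuple[float, str]:
    """Score phase-space topology: 1 = point-like (fixed point), 0 = ring-like.

    ``level`` is the density threshold as a fraction of the density maximum;
    ``cover_limit`` is the grid-area fraction above which the high-occupancy
    set is considered structureless and the result indeterminate.
    Returns (score, classification) with classification one of "point-like",
    "ring-like", "indeterminate".
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    high = pd_.density >= level * pd_.density.max()
    area = high.mean()
    if area > cover_limit:
        return 0.5, "indeterminate"
    filled = ndimage.binary_fill_holes(high)
    score = float(high.sum() / filled.sum())
    label = "point-like" if score >= 0.5 else "ring-like"
    return score, label
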