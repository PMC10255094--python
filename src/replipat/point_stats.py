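"""Distance and location statistics for gold-particle patterns.

Same-channel and cross-channel nearest-neighbor distances (NND), all
pairwise distances (APD), the center-periphery index (CPI, the squared
normalized radial distance from the ROI center of gravity: 0 at the center,
1 at the edge, mean ~0.5 for points randomly distributed in a circle),
sample skewness, and the closed-form expected mean NND under complete
spatial randomness (CSR), 0.5/sqrt(density).

No edge correction is applied to NND/APD, matching the convention of the
replica-labeling studies this package targets; the bias is negligible for
ROIs much larger than the mean NND.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import skew

from shapely.geometry import Point

from replipat.geometry import ParticleSet, RimSpec, RoiPolygon, _contains_mask, \
    contains_with_rim, ray_normalized_positions

__all__ = [
    "DistanceSample",
    "CpiSample",
    "nnd_same",
    "nnd_cross",
    "all_pairwise_distances",
    "cpi",
    "expected_nnd_csr",
    "sample_skewness",
]


@dataclass(frozen=True)
class DistanceSample:
    """A bag of distances (nm) of one kind from one ROI."""

    values: np.ndarray
    kind: str  # NND_same | NND_cross | APD
    source_roi: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if np.any(v < 0):
            raise ValueError("distances must be >= 0")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class CpiSample:
    """Per-particle center-periphery indices (each in [0, 1]) and their mean."""

    values: np.ndarray
    source_roi: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("CPI values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def mean_cpi(self) -> float:
        return float(np.mean(self.values))


def nnd_same(ps: ParticleSet) -> DistanceSample:
    """Nearest-neighbor distance from each particle to any other particle of
    the same set (channel). Requires at least two particles."""
    if len(ps) < 2:
        raise ValueError("nnd_same needs at least 2 points")
    tree = cKDTree(ps.points)
    d, _ = tree.query(ps.points, k=2)
    return DistanceSample(d[:, 1], kind="NND_same", source_roi=ps.roi_id)


def nnd_cross(from_ps: ParticleSet, to_ps: ParticleSet) -> DistanceSample:
    """Nearest-neighbor distance from each particle of ``from_ps`` to the
    closest particle of ``to_ps`` (asymmetric; no self-exclusion — the two
    sets are distinct channels)."""
    if len(to_ps) == 0:
        raise ValueError("nnd_cross needs a nonempty target set")
    if len(from_ps) == 0:
        raise ValueError("nnd_cross needs a nonempty source set")
    tree = cKDTree(to_ps.points)
    d, _ = tree.query(from_ps.points, k=1)
    return DistanceSample(np.atleast_1d(d), kind="NND_cross",
                          source_roi=from_ps.roi_id)


def all_pairwise_distances(ps: ParticleSet) -> DistanceSample:
    """All n(n-1)/2 unordered pairwise distances within a set."""
    if len(ps) < 2:
        raise ValueError("all_pairwise_distances needs at least 2 points")
    return DistanceSample(pdist(ps.points), kind="APD", source_roi=ps.roi_id)


def cpi(ps: ParticleSet, roi: RoiPolygon, rim: RimSpec | None = None) -> CpiSample:
    """Center-periphery index per particle: squared normalized radial distance
    from the ROI center of gravity.

    Particles admitted to an AZ by the outer-rim rule but lying outside the
    polygon are assigned CPI = 1 (maximally peripheral). Particles outside
    the ROI and outside any rim raise an error.
    """
    if len(ps) == 0:
        raise ValueError("cpi needs at least one particle")
    if not roi.polygon.covers(Point(roi.centroid)):
        raise ValueError(
            "CPI undefined: ROI centroid lies outside the (non-convex) polygon"
        )
    inside = _contains_mask(ps.points, roi, None)
    vals = np.empty(len(ps))
    vals[inside] = ray_normalized_positions(ps.points[inside], roi) ** 2
    for i in np.nonzero(~inside)[0]:
        if rim is not None and contains_with_rim(ps.points[i], roi, rim):
            vals[i] = 1.0  # rim particle: boundary class
        else:
            raise ValueError(f"particle {i} lies outside the ROI (and rim)")
    return CpiSample(vals, source_roi=ps.roi_id)


def expected_nnd_csr(density: float) -> float:
    """Expected mean nearest-neighbor distance (nm) of a homogeneous Poisson
    pattern of the given intensity (per nm²): 0.5/sqrt(density)."""
    if density <= 0:
        raise ValueError("density must be > 0")
    return 0.5 / np.sqrt(density)


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness (third standardized moment)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 3:
        raise ValueError("skewness needs at least 3 values")
    if np.var(v) == 0:
        raise ValueError("skewness undefined for zero-variance sample")
    return float(skew(v, bias=False))
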