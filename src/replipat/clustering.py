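"""Particle-cluster detection and geometry.

Clusters of gold particles are detected either with DBSCAN (minimum cluster
size 3; neighborhood radius eps set per ROI to the median plus 1.5 times
the interquartile range of the same-channel nearest-neighbor distances) or
with Ward-linkage hierarchical clustering cut at a 50-nm dendrogram height.
A cluster's area is the area of the convex polygon connecting its outermost
particles; the intracluster density is members per hull area. The
postsynaptic density (PSD) of a spine is demarcated operationally as the
convex hull of the largest marker-channel (e.g. GluD2) cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import DBSCAN

from replipat.geometry import ParticleSet, RoiPolygon, polygon_area
from replipat.point_stats import DistanceSample, nnd_same

NOISE = -1

__all__ = [
    "NOISE",
    "ClusterAssignment",
    "ClusterSummary",
    "eps_from_nnd",
    "dbscan_clusters",
    "ward_clusters",
    "cluster_hull_area",
    "summarize_clusters",
    "psd_from_marker",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-particle cluster labels (-1 = noise) for one particle set."""

    labels: np.ndarray
    method: str  # "dbscan" | "ward50"
    particle_set: ParticleSet
    eps_used: float | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.size != len(self.particle_set):
            raise ValueError("one label per particle required")
        object.__setattr__(self, "labels", lab)

    @property
    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != NOISE]

    @property
    def n_clusters(self) -> int:
        return self.cluster_ids.size

    def members(self, cluster_id: int) -> np.ndarray:
        return self.particle_set.points[self.labels == cluster_id]


@dataclass(frozen=True)
class ClusterSummary:
    """Geometry of one detected cluster: member count, convex-hull area
    (nm²), and intracluster particle density (per nm²; NaN for degenerate
    zero-area hulls)."""

    cluster_id: int
    n_particles: int
    hull_area: float
    intracluster_density: float
    degenerate: bool = False


def eps_from_nnd(nnds: DistanceSample | np.ndarray) -> float:
    """DBSCAN neighborhood radius: median + 1.5 * IQR of the nearest-neighbor
    distances (quartiles by linear interpolation)."""
    v = nnds.values if isinstance(nnds, DistanceSample) else \
        np.asarray(nnds, dtype=float).ravel()
    if v.size < 4:
        raise ValueError("eps_from_nnd needs at least 4 NND values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med + 1.5 * (q3 - q1))


def _sorted_for_determinism(ps: ParticleSet) -> tuple[ParticleSet, np.ndarray]:
    order = np.lexsort((ps.points[:, 1], ps.points[:, 0]))
    return ParticleSet(ps.points[order], ps.channel, ps.roi_id), order


def dbscan_clusters(
    ps: ParticleSet, min_pts: int = 3, eps: float | None = None
) -> ClusterAssignment:
    """DBSCAN cluster labels with minimum cluster size ``min_pts`` (default
    3). ``eps`` defaults to the median+1.5*IQR rule applied to this set's
    own nearest-neighbor distances. Points are processed in coordinate
    order so border-point assignment is deterministic."""
    if eps is None:
        eps = eps_from_nnd(nnd_same(ps))
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if len(ps) == 0:
        return ClusterAssignment(np.empty(0, int), "dbscan", ps, eps)
    sorted_ps, order = _sorted_for_determinism(ps)
    lab_sorted = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(
        sorted_ps.points
    )
    labels = np.empty(len(ps), dtype=int)
    labels[order] = lab_sorted
    return ClusterAssignment(labels, "dbscan", ps, eps)


def ward_clusters(ps: ParticleSet, cutoff: float = 50.0) -> ClusterAssignment:
    """Ward-linkage agglomerative clustering, dendrogram cut at ``cutoff`` nm
    cophenetic height (default 50 nm). Every particle is assigned to a
    cluster (singletons allowed)."""
    if len(ps) < 1:
        raise ValueError("ward_clusters needs at least one point")
    if len(ps) == 1:
        return ClusterAssignment(np.zeros(1, int), "ward50", ps)
    Z = linkage(ps.points, method="ward")
    labels = fcluster(Z, t=cutoff, criterion="distance") - 1
    return ClusterAssignment(labels, "ward50", ps)


def cluster_hull_area(member_points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull area (nm²) of a cluster's member coordinates.

    Returns ``(area, degenerate)``; clusters with fewer than three members
    or with collinear members have zero area and are flagged degenerate.
    """
    pts = np.atleast_2d(np.asarray(member_points, dtype=float))
    if len(pts) < 3:
        return 0.0, True
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False  # in 2-D, .volume is the area


def summarize_clusters(
    assignment: ClusterAssignment, roi: RoiPolygon
) -> tuple[list[ClusterSummary], float]:
    """Per-cluster geometry plus the per-ROI cluster density (clusters/µm²).

    Degenerate (zero-hull-area) clusters report NaN intracluster density and
    are flagged; they still count toward the cluster density.
    """
    summaries = []
    for cid in assignment.cluster_ids:
        pts = assignment.members(int(cid))
        area, degen = cluster_hull_area(pts)
        dens = len(pts) / area if area > 0 else float("nan")
        summaries.append(
            ClusterSummary(int(cid), len(pts), area, dens, degenerate=degen)
        )
    cluster_density = len(summaries) / polygon_area(roi) * 1e6
    return summaries, cluster_density


def psd_from_marker(
    marker_ps: ParticleSet,
    spine_roi: RoiPolygon,
    min_pts: int = 3,
    eps: float | None = None,
) -> RoiPolygon:
    """Demarcate the postsynaptic density as the convex hull of the largest
    marker-channel cluster on the spine (DBSCAN, same eps rule unless an
    explicit ``eps`` is given).

    Ties in member count are broken toward the larger hull area. Raises if
    no cluster of at least ``min_pts`` markers with a non-degenerate hull
    exists (PSD undefined).
    """
    if len(marker_ps) == 0:
        raise ValueError("marker channel is empty; PSD undefined")
    if eps is None and len(marker_ps) < 4:
        raise ValueError("too few marker particles to set eps; PSD undefined")
    assignment = dbscan_clusters(marker_ps, min_pts=min_pts, eps=eps)
    best = None
    for cid in assignment.cluster_ids:
        pts = assignment.members(int(cid))
        area, degenerate = cluster_hull_area(pts)
        if degenerate:
            continue
        key = (len(pts), area)
        if best is None or key > best[0]:
            best = (key, pts)
    if best is None:
        raise ValueError("no marker cluster of >= 3 particles; PSD undefined")
    pts = best[1]
    hull = ConvexHull(pts)
    verts = tuple(map(tuple, pts[hull.vertices]))
    return RoiPolygon(
        vertices=verts,
        kind="PSD",
        face=spine_roi.face,
        id=f"{spine_roi.id}:PSD" if spine_roi.id else "PSD",
        image_id=spine_roi.image_id,
    )
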