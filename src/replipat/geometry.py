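"""ROI polygons, containment with the active-zone outer rim, and radial coordinates.

All coordinates are continuous nanometres in image-local axes. Regions of
interest (ROIs) are simple planar polygons demarcating membrane patches
(somata, dendritic compartments, spines, boutons, active zones, postsynaptic
densities). Gold particles belonging to an active zone (AZ) include those
within a 30-nm outer rim beyond the demarcation border; all other ROI kinds
use plain containment.

The normalized radial position underlies the center-periphery index (CPI):
0 at the ROI center of gravity, 1 on the boundary, measured along the ray
from the centroid through the point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely import contains_xy
from shapely.geometry import Point, Polygon

ROI_KINDS = frozenset(
    {"soma", "MS", "SmB", "SpB", "spine", "bouton", "AZ", "PSD", "other"}
)
FACES = frozenset({"P", "E"})

__all__ = [
    "ROI_KINDS",
    "FACES",
    "RoiPolygon",
    "ParticleSet",
    "RimSpec",
    "polygon_area",
    "contains_with_rim",
    "normalized_radial_position",
    "ray_normalized_positions",
    "particle_density",
]


@dataclass(frozen=True)
class RoiPolygon:
    """A demarcated membrane region: simple polygon with kind and fracture face.

    Parameters
    ----------
    vertices
        Ordered (x, y) vertex coordinates in nm; at least three, forming a
        simple (non-self-intersecting) polygon of positive area.
    kind
        Compartment label: one of ``soma, MS, SmB, SpB, spine, bouton, AZ,
        PSD, other``.
    face
        Fracture face, ``"P"`` (protoplasmic) or ``"E"`` (exoplasmic).
    """

    vertices: tuple[tuple[float, float], ...]
    kind: str = "other"
    face: str = "P"
    id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("RoiPolygon needs at least 3 vertices")
        if not np.all(np.isfinite(np.asarray(verts))):
            raise ValueError("RoiPolygon vertices must be finite")
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.face not in FACES:
            raise ValueError(f"unknown face {self.face!r}; expected P or E")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError("RoiPolygon must be a simple polygon")
        if poly.area <= 0:
            raise ValueError("RoiPolygon is degenerate (zero area)")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_nm2(self) -> float:
        return polygon_area(self)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


@dataclass(frozen=True)
class ParticleSet:
    """Planar gold-particle coordinates (nm) of one channel within one ROI."""

    points: np.ndarray
    channel: str
    roi_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of nm coordinates")
        if not np.all(np.isfinite(pts)):
            raise ValueError("particle coordinates must be finite")
        if not self.channel:
            raise ValueError("channel must be nonempty")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class RimSpec:
    """Outer-rim rule for AZ membership: particles inside the demarcation or
    strictly closer than ``rim_width`` nm to its border count as AZ particles."""

    rim_width: float = 30.0

    def __post_init__(self) -> None:
        if self.rim_width < 0:
            raise ValueError("rim_width must be >= 0")


def polygon_area(roi: RoiPolygon) -> float:
    """Shoelace area of the ROI polygon in nm², independent of orientation."""
    area = Polygon(roi.vertices).area
    if area <= 0:
        raise ValueError("degenerate polygon: zero area")
    return float(area)


def contains_with_rim(
    point: Sequence[float], roi: RoiPolygon, rim: RimSpec | None = None
) -> bool:
    """True iff ``point`` lies inside the ROI (boundary inclusive) or strictly
    within ``rim.rim_width`` nm of its border.

    With ``rim=None`` (or width 0) this is plain closed-region containment.
    """
    p = Point(float(point[0]), float(point[1]))
    poly = roi.polygon
    if poly.covers(p):
        return True
    if rim is None or rim.rim_width == 0:
        return False
    return poly.exterior.distance(p) < rim.rim_width


def _contains_mask(
    points: np.ndarray, roi: RoiPolygon, rim: RimSpec | None
) -> np.ndarray:
    """Vectorized containment (closed region, optional rim) for an (n, 2) array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = roi.polygon
    inside = contains_xy(poly, pts[:, 0], pts[:, 1])
    # contains_xy excludes the boundary; include points exactly on it,
    # plus (when a rim applies) points strictly within the rim of the border
    outside = np.nonzero(~inside)[0]
    if outside.size:
        d = shapely.distance(poly.exterior, shapely.points(pts[outside]))
        hit = d == 0.0
        if rim is not None:
            hit |= d < rim.rim_width
        inside[outside[hit]] = True
    return inside


def _ray_boundary_distances(
    points: np.ndarray, centroid: np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """Distance from ``centroid`` to the first polygon-boundary crossing along
    the ray through each point. Vectorized over points and edges.

    Points coincident with the centroid get distance inf (their radial
    position is 0 regardless).
    """
    pts = np.atleast_2d(points)
    r = pts - centroid
    dist = np.hypot(r[:, 0], r[:, 1])
    u = np.where(dist[:, None] > 0, r / np.maximum(dist, 1e-300)[:, None], 0.0)
    a = vertices
    b = np.roll(vertices, -1, axis=0)
    e = b - a  # (m, 2)
    ac = a - centroid  # (m, 2)
    # solve centroid + t*u = a + s*e for each (point, edge)
    denom = u[:, 0, None] * e[None, :, 1] - u[:, 1, None] * e[None, :, 0]
    num_t = ac[None, :, 0] * e[None, :, 1] - ac[None, :, 1] * e[None, :, 0]
    num_s = ac[None, :, 0] * u[:, 1, None] - ac[None, :, 1] * u[:, 0, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num_t / denom
        s = num_s / denom
    eps = 1e-9
    valid = (np.abs(denom) > 1e-300) & (t > eps) & (s >= -eps) & (s <= 1 + eps)
    t = np.where(valid, t, np.inf)
    tmin = t.min(axis=1)
    tmin = np.where(dist > 0, tmin, np.inf)
    return tmin


def ray_normalized_positions(points: np.ndarray, roi: RoiPolygon) -> np.ndarray:
    """Normalized radial position (0 center, 1 boundary) for an array of
    points assumed inside the ROI; vectorized companion of
    :func:`normalized_radial_position` (no containment check)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = roi.centroid
    verts = np.asarray(roi.vertices)
    out = np.empty(len(pts))
    chunk = 20_000  # bound the (points x edges) intermediate arrays
    for lo in range(0, len(pts), chunk):
        sub = pts[lo : lo + chunk]
        t = _ray_boundary_distances(sub, c, verts)
        d = np.hypot(sub[:, 0] - c[0], sub[:, 1] - c[1])
        with np.errstate(invalid="ignore"):
            v = np.where(d > 0, np.minimum(d / t, 1.0), 0.0)
        out[lo : lo + chunk] = v
    return out


def normalized_radial_position(point: Sequence[float], roi: RoiPolygon) -> float:
    """Distance of ``point`` from the ROI centroid, normalized by the
    centroid-to-boundary distance along the ray through the point.

    Returns 0 at the center of gravity and 1 on the boundary. For a point in
    a non-convex ROI whose centroid falls outside the region, the maximum
    boundary distance is used as the normalizer instead (with a warning);
    the compact AZ/PSD patches this statistic targets do not hit that path.
    """
    p = np.asarray(point, dtype=float)
    poly = roi.polygon
    if not _contains_mask(p[None, :], roi, None)[0]:
        raise ValueError("point lies outside the ROI")
    c = roi.centroid
    r = p - c
    dist = float(np.hypot(*r))
    if dist == 0.0:
        return 0.0
    if not poly.covers(Point(c)):
        warnings.warn(
            "ROI centroid lies outside the (non-convex) polygon; "
            "normalizing by the maximum boundary distance",
            stacklevel=2,
        )
        verts = np.asarray(roi.vertices)
        rmax = float(np.max(np.hypot(verts[:, 0] - c[0], verts[:, 1] - c[1])))
        return min(dist / rmax, 1.0)
    return float(ray_normalized_positions(p[None, :], roi)[0])


def particle_density(
    ps: ParticleSet, roi: RoiPolygon, rim: RimSpec | None = None
) -> float:
    """Particles per µm²: contained-particle count over the polygon area.

    The rim rule is applied only for AZ-kind ROIs (gold particles inside or
    strictly closer than the rim width to the AZ border are counted).
    """
    area = polygon_area(roi)
    effective_rim = rim if roi.kind == "AZ" else None
    if len(ps) == 0:
        return 0.0
    count = int(np.count_nonzero(_contains_mask(ps.points, roi, effective_rim)))
    return count / area * 1e6
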