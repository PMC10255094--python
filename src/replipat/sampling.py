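"""Uniform random sampling inside polygons (rejection from the bounding box)."""

from __future__ import annotations

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon

from replipat.geometry import RoiPolygon

__all__ = ["as_rng", "sample_uniform_in_polygon"]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_uniform_in_polygon(
    poly: RoiPolygon | Polygon, n: int, rng=None
) -> np.ndarray:
    """Draw ``n`` points uniformly distributed inside a polygon.

    Rejection sampling from the axis-aligned bounding box; the expected
    number of proposals is n / (area fraction of the box covered).
    """
    rng = as_rng(rng)
    geom = poly.polygon if isinstance(poly, RoiPolygon) else poly
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    frac = max(geom.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    out = np.empty((0, 2))
    while len(out) < n:
        m = int((n - len(out)) / frac * 1.2) + 16
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = contains_xy(geom, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]
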