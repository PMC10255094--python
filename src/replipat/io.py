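"""Readers and writers: particle CSV tables and ROI GeoJSON polygons.

Particles travel as tidy CSV with columns ``image_id, roi_id, channel,
x_nm, y_nm``; ROIs as a GeoJSON FeatureCollection of Polygon features with
properties ``roi_id, image_id, kind, face``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from replipat.geometry import FACES, ROI_KINDS, ParticleSet, RoiPolygon

PARTICLE_COLUMNS = ["image_id", "roi_id", "channel", "x_nm", "y_nm"]

__all__ = [
    "PARTICLE_COLUMNS",
    "read_particles",
    "write_particles",
    "read_rois",
    "write_rois",
]


def read_particles(path: str | Path) -> list[ParticleSet]:
    """Read a particle CSV and group it into one ParticleSet per
    (image, ROI, channel).

    Malformed rows (non-numeric coordinates) are reported with their file
    line numbers; missing columns raise immediately.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "roi_id": str, "channel": str})
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    x = pd.to_numeric(df["x_nm"], errors="coerce")
    y = pd.to_numeric(df["y_nm"], errors="coerce")
    bad = df.index[x.isna() | y.isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(
            f"{path}: non-numeric coordinates on line(s) {lines}"
            + (" ..." if len(bad) > 10 else "")
        )
    df = df.assign(x_nm=x, y_nm=y)
    if df.empty:
        import warnings

        warnings.warn(f"{path}: no particle rows", stacklevel=2)
        return []
    out = []
    for (image_id, roi_id, channel), g in df.groupby(
        ["image_id", "roi_id", "channel"], sort=True
    ):
        out.append(
            ParticleSet(
                g[["x_nm", "y_nm"]].to_numpy(float),
                channel=channel,
                roi_id=roi_id,
                image_id=image_id,
            )
        )
    return out


def write_particles(sets: list[ParticleSet], path: str | Path) -> None:
    """Write particle sets back to the tidy CSV schema (full float precision)."""
    rows = []
    for ps in sets:
        for x, y in ps.points:
            rows.append(
                {"image_id": ps.image_id, "roi_id": ps.roi_id,
                 "channel": ps.channel, "x_nm": repr(float(x)),
                 "y_nm": repr(float(y))}
            )
    pd.DataFrame(rows, columns=PARTICLE_COLUMNS).to_csv(path, index=False)


def _roi_from_feature(feat: dict, source: str) -> RoiPolygon:
    geom = feat.get("geometry") or {}
    if geom.get("type") != "Polygon":
        raise ValueError(f"{source}: only Polygon features are supported")
    rings = geom.get("coordinates") or []
    if not rings:
        raise ValueError(f"{source}: polygon feature without coordinates")
    ring = rings[0]
    # GeoJSON closes the ring; RoiPolygon wants it open
    if len(ring) >= 2 and ring[0] == ring[-1]:
        ring = ring[:-1]
    props = feat.get("properties") or {}
    kind = props.get("kind", "other")
    if kind not in ROI_KINDS:
        raise ValueError(f"{source}: unknown ROI kind {kind!r}")
    face = props.get("face", "P")
    if face not in FACES:
        raise ValueError(f"{source}: unknown face {face!r}")
    return RoiPolygon(
        vertices=tuple((float(x), float(y)) for x, y in ring),
        kind=kind,
        face=face,
        id=str(props.get("roi_id", "")),
        image_id=str(props.get("image_id", "")),
    )


def read_rois(path: str | Path) -> list[RoiPolygon]:
    """Read ROI polygons from a GeoJSON FeatureCollection.

    Validates geometry, kind, and face; when an image carries both AZ and
    bouton (or PSD and spine) ROIs, each nested region must lie inside a
    parent of the matching kind.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features")
    if doc.get("type") != "FeatureCollection" or feats is None:
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    rois = [
        _roi_from_feature(f, f"{path} feature {i}") for i, f in enumerate(feats)
    ]
    _check_nesting(rois, str(path))
    return rois


def _check_nesting(rois: list[RoiPolygon], source: str) -> None:
    for child_kind, parent_kind in (("AZ", "bouton"), ("PSD", "spine")):
        by_image: dict[str, list[RoiPolygon]] = {}
        for r in rois:
            if r.kind == parent_kind:
                by_image.setdefault(r.image_id, []).append(r)
        for r in rois:
            if r.kind != child_kind:
                continue
            parents = by_image.get(r.image_id, [])
            if not parents:
                continue
            if not any(p.polygon.covers(r.polygon) for p in parents):
                raise ValueError(
                    f"{source}: {child_kind} ROI {r.id!r} is not contained "
                    f"in any {parent_kind} ROI of image {r.image_id!r}"
                )


def write_rois(rois: list[RoiPolygon], path: str | Path) -> None:
    """Write ROI polygons as a GeoJSON FeatureCollection."""
    feats = []
    for r in rois:
        ring = [[float(x), float(y)] for x, y in r.vertices]
        ring.append(ring[0])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "roi_id": r.id,
                    "image_id": r.image_id,
                    "kind": r.kind,
                    "face": r.face,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
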