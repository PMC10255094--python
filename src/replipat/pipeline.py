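"""Pipeline driver: run the full per-ROI analysis over a study dataset.

Ties the stages together: particle density, distance statistics (NND/APD
summaries, skewness), center-periphery index, cluster detection and
summaries, the random-simulation null comparison of mean NND, and the
Gaussian-mixture decomposition of NNDs. Emits tidy per-ROI and per-cluster
tables carrying full provenance (image, ROI, channel, seed) plus a run
manifest; hierarchical statistics across ROIs are intentionally left to
external tools.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from replipat.clustering import dbscan_clusters, summarize_clusters
from replipat.density_models import gmm_nnd
from replipat.geometry import (
    ParticleSet,
    RimSpec,
    RoiPolygon,
    _contains_mask,
    particle_density,
)
from replipat.io import read_particles, read_rois
from replipat.null_models import RandomSimConfig, compare_real_vs_sim_nnd
from replipat.point_stats import cpi, nnd_same, sample_skewness
from replipat.sampling import as_rng

logger = logging.getLogger("replipat")

__all__ = ["StudyConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the ROI."""


def _package_version() -> str:
    import replipat

    return replipat.__version__


@dataclass
class StudyConfig:
    """Configuration of one pipeline run.

    Input either as file paths (``particles_path`` CSV + ``rois_path``
    GeoJSON) or as in-memory objects (``particle_sets``, ``rois``).
    ``channel_map`` assigns each channel a role (``target``, ``marker``, or
    ``association``); only ``target`` channels are analyzed by this driver.
    """

    particles_path: str | None = None
    rois_path: str | None = None
    particle_sets: list[ParticleSet] | None = None
    rois: list[RoiPolygon] | None = None
    channel_map: dict[str, str] = field(default_factory=lambda: {"target": "target"})
    rim: RimSpec = field(default_factory=RimSpec)
    random_sim: RandomSimConfig = field(default_factory=RandomSimConfig)
    n_null_replicates: int = 20
    min_pts: int = 3
    gmm_min_values: int = 20
    seed: int = 0
    output_dir: str | None = None

    def load(self) -> tuple[list[ParticleSet], list[RoiPolygon]]:
        ps = self.particle_sets
        rois = self.rois
        if ps is None:
            if self.particles_path is None:
                raise ValueError("StudyConfig needs particle_sets or particles_path")
            ps = read_particles(self.particles_path)
        if rois is None:
            if self.rois_path is None:
                raise ValueError("StudyConfig needs rois or rois_path")
            rois = read_rois(self.rois_path)
        roles = set(self.channel_map.values())
        bad = roles - {"target", "marker", "association"}
        if bad:
            raise ValueError(f"unknown channel roles {sorted(bad)}")
        channels = {p.channel for p in ps}
        unmapped = channels - set(self.channel_map)
        if unmapped:
            raise ValueError(f"channels without a role: {sorted(unmapped)}")
        return ps, rois


def run_pipeline(cfg: StudyConfig) -> dict[str, Any]:
    """Run every stage per (target-channel) ROI and return the result bundle:
    ``roi_summary``, ``clusters``, ``null_nnd``, ``gmm``, and ``manifest``.

    Deterministic given ``cfg.seed``; any stage error aborts with the stage
    name and ROI id. If ``cfg.output_dir`` is set, tables are written there
    as CSV (refusing to overwrite an existing non-empty directory).
    """
    t0 = time.time()
    particle_sets, rois = cfg.load()
    roi_by_id = {r.id: r for r in rois}
    rng = as_rng(cfg.seed)
    targets = [
        p for p in particle_sets
        if cfg.channel_map.get(p.channel) == "target"
    ]
    logger.info(
        "pipeline start: %d target sets, %d ROIs, seed=%d",
        len(targets), len(rois), cfg.seed,
    )

    summary_rows, cluster_rows, null_frames, gmm_rows = [], [], [], []
    for ps in targets:
        roi = roi_by_id.get(ps.roi_id)
        if roi is None:
            raise PipelineError(f"stage=lookup roi={ps.roi_id!r}: ROI not found")
        prov = {"image_id": ps.image_id, "roi_id": ps.roi_id,
                "channel": ps.channel, "seed": cfg.seed}
        row = dict(prov)
        try:
            row["density_um2"] = particle_density(ps, roi, cfg.rim)
            inside = _contains_mask(ps.points, roi, None)
            row["n_particles"] = int(len(ps))
            row["n_inside"] = int(inside.sum())
            nnds = nnd_same(ps) if len(ps) >= 2 else None
            row["mean_nnd_nm"] = nnds.mean if nnds is not None else np.nan
            row["nnd_skewness"] = (
                sample_skewness(nnds.values)
                if nnds is not None and len(nnds) >= 3
                and np.var(nnds.values) > 0 else np.nan
            )
            if inside.any():
                ps_in = ParticleSet(ps.points[inside], ps.channel,
                                    ps.roi_id, ps.image_id)
                row["mean_cpi"] = cpi(ps_in, roi).mean_cpi
            else:
                row["mean_cpi"] = np.nan
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage=point_stats roi={ps.roi_id!r}: {exc}"
            ) from exc

        try:
            if len(ps) >= 4:
                assignment = dbscan_clusters(ps, min_pts=cfg.min_pts)
                summaries, cluster_density = summarize_clusters(assignment, roi)
                row["cluster_density_um2"] = cluster_density
                row["eps_nm"] = assignment.eps_used
                for s in summaries:
                    cluster_rows.append(
                        {**prov, "cluster_id": s.cluster_id,
                         "n_particles": s.n_particles,
                         "hull_area_nm2": s.hull_area,
                         "intracluster_density_nm2": s.intracluster_density,
                         "degenerate": s.degenerate}
                    )
            else:
                row["cluster_density_um2"] = np.nan
                row["eps_nm"] = np.nan
        except Exception as exc:
            raise PipelineError(
                f"stage=clustering roi={ps.roi_id!r}: {exc}"
            ) from exc

        try:
            if len(ps) >= 2 and cfg.n_null_replicates > 0:
                df = compare_real_vs_sim_nnd(
                    ps, roi, "random", cfg.random_sim,
                    n_replicates=cfg.n_null_replicates, rng=rng,
                )
                for k, v in prov.items():
                    df[k] = v
                null_frames.append(df)
        except Exception as exc:
            raise PipelineError(
                f"stage=null_model roi={ps.roi_id!r}: {exc}"
            ) from exc

        try:
            if nnds is not None and len(nnds) >= cfg.gmm_min_values:
                fit = gmm_nnd(nnds, seed=cfg.seed)
                gmm_rows.append(
                    {**prov, "mean_short_nm": fit.means[0],
                     "mean_long_nm": fit.means[1], "sd_short_nm": fit.sds[0],
                     "sd_long_nm": fit.sds[1], "weight_short": fit.weights[0],
                     "weight_long": fit.weights[1],
                     "converged": fit.converged, "degenerate": fit.degenerate}
                )
        except Exception as exc:
            raise PipelineError(f"stage=gmm roi={ps.roi_id!r}: {exc}") from exc
        summary_rows.append(row)
        logger.debug("roi %s done", ps.roi_id)

    bundle = {
        "roi_summary": pd.DataFrame(summary_rows),
        "clusters": pd.DataFrame(cluster_rows),
        "null_nnd": pd.concat(null_frames, ignore_index=True)
        if null_frames else pd.DataFrame(),
        "gmm": pd.DataFrame(gmm_rows),
        "manifest": {
            "package_version": _package_version(),
            "seed": cfg.seed,
            "n_rois": len(rois),
            "n_target_sets": len(targets),
            "rim_width_nm": cfg.rim.rim_width,
            "random_sim": {
                "min_distance": cfg.random_sim.min_distance,
                "displacement_diameter": cfg.random_sim.displacement_diameter,
            },
            "n_null_replicates": cfg.n_null_replicates,
            "elapsed_s": round(time.time() - t0, 3),
        },
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("roi_summary", "clusters", "null_nnd", "gmm"):
            dest = out / f"{name}.csv"
            if dest.exists():
                raise PipelineError(
                    f"stage=write: refusing to overwrite {dest}"
                )
            bundle[name].to_csv(dest, index=False)
        import json

        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2)
    logger.info("pipeline done in %.2fs", time.time() - t0)
    return bundle
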