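"""End-to-end pipeline on a generated multi-compartment study.

Generates a small multi-ROI dataset (soma/dendrite/spine compartments with
their measured density presets), round-trips it through the CSV/GeoJSON
readers, and runs the full per-ROI analysis: density, NND statistics, CPI,
DBSCAN cluster summaries, the random-simulation null comparison, and GMM
fits. The output tables are the input to external hierarchical statistics.
"""

import tempfile
from pathlib import Path

from replipat import (
    StudyConfig,
    gen_study,
    read_particles,
    run_pipeline,
    write_rois,
)

ds = gen_study(n_rois_per_compartment=2, seed=11, roi_area=2.0)

with tempfile.TemporaryDirectory() as tmp:
    particles_csv = Path(tmp) / "particles.csv"
    rois_geojson = Path(tmp) / "rois.geojson"
    ds["particles"].to_csv(particles_csv, index=False)
    write_rois(ds["rois"], rois_geojson)

    cfg = StudyConfig(
        particles_path=str(particles_csv),
        rois_path=str(rois_geojson),
        seed=0,
        n_null_replicates=5,
    )
    bundle = run_pipeline(cfg)

summary = bundle["roi_summary"]
print(summary[["roi_id", "density_um2", "mean_nnd_nm",
               "cluster_density_um2"]].to_string(index=False))
print(f"\n{len(bundle['clusters'])} clusters, "
      f"{len(bundle['null_nnd'])} null-comparison rows, "
      f"{len(bundle['gmm'])} GMM fits")
per_comp = summary.assign(comp=summary.roi_id.str.split("_").str[0]) \
    .groupby("comp").density_um2.mean().round(1)
print("\nmean density by compartment (particles/um^2):")
print(per_comp.to_string())
print("spine membranes carry the highest particle density, "
      "matching the generator presets")
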