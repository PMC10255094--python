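"""Cluster detection: DBSCAN with the data-driven eps rule, Ward linkage,
and PSD demarcation from a marker channel.

eps for DBSCAN is the median + 1.5 IQR of the pattern's nearest-neighbor
distances; clusters need at least 3 members. Ward-linkage clustering cuts
the dendrogram at 50 nm. The postsynaptic density (PSD) of a spine is
demarcated as the convex hull of the largest marker cluster.
"""

import numpy as np

from replipat import (
    ParticleSet,
    SceneSpec,
    dbscan_clusters,
    gen_pattern,
    gen_roi,
    psd_from_marker,
    summarize_clusters,
    ward_clusters,
)

spec = SceneSpec(roi_area=4.0, global_density=73.7,
                 intracluster_density=0.0137, seed=21)  # spine-like preset
roi = gen_roi(spec)
ps, truth = gen_pattern(roi, spec)

db = dbscan_clusters(ps)
summaries, cluster_density = summarize_clusters(db, roi)
areas = [s.hull_area for s in summaries if not s.degenerate]
intra = [s.intracluster_density for s in summaries if not s.degenerate]
print(f"DBSCAN (minPts 3, eps {db.eps_used:.0f} nm): "
      f"{db.n_clusters} clusters, {(db.labels == -1).sum()} noise particles")
print(f"cluster density {cluster_density:.1f} /um^2, "
      f"mean hull area {np.mean(areas):.0f} nm^2, "
      f"mean intracluster density {np.mean(intra):.4f} /nm^2")

ward = ward_clusters(ps, cutoff=50.0)
print(f"Ward linkage at 50 nm: {ward.n_clusters} clusters "
      "(every particle assigned; singletons allowed)")

# PSD from a synthetic marker channel: a tight 12-particle patch plus noise
rng = np.random.default_rng(5)
marker_pts = np.vstack([
    roi.centroid + rng.normal(scale=25.0, size=(12, 2)),
    rng.uniform(-800, 800, size=(6, 2)) + roi.centroid,
])
psd = psd_from_marker(ParticleSet(marker_pts, channel="GluD2"), roi)
print(f"PSD demarcated from the largest marker cluster: "
      f"{psd.area_nm2:.0f} nm^2 ({psd.kind}-kind ROI)")
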