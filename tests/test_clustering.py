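import numpy as np
import pytest

from replipat import (
    ParticleSet,
    RoiPolygon,
    cluster_hull_area,
    dbscan_clusters,
    eps_from_nnd,
    psd_from_marker,
    summarize_clusters,
    ward_clusters,
)

# ---------------------------------------------------------------------------
# independent oracles


def dbscan_oracle(points, eps, min_pts):
    """Exhaustive density-reachability DBSCAN: returns a partition as a set
    of frozensets (noise points excluded)."""
    n = len(points)
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    neighbors = [set(np.nonzero(d[i] <= eps)[0]) for i in range(n)]
    core = [i for i in range(n) if len(neighbors[i]) >= min_pts]
    # connected components of core points under eps-adjacency
    unassigned = set(core)
    clusters = []
    while unassigned:
        seed = unassigned.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            for j in list(unassigned):
                if j in neighbors[i]:
                    unassigned.discard(j)
                    comp.add(j)
                    frontier.append(j)
        clusters.append(comp)
    # attach border points to any reaching core cluster
    for i in range(n):
        if i in core:
            continue
        for comp in clusters:
            if neighbors[i] & comp & set(core):
                comp.add(i)
                break
    return {frozenset(c) for c in clusters}


def ward_lance_williams(points, cutoff):
    """Brute-force Ward agglomeration via the Lance-Williams recurrence,
    merging while the merge distance stays below the cutoff; returns the
    partition as a set of frozensets."""
    n = len(points)
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((points[i] - points[j]) ** 2).sum())
    next_id = n
    while len(clusters) > 1:
        (a, b), best = min(d2.items(), key=lambda kv: kv[1])
        if np.sqrt(best) > cutoff:
            break
        na, nb = sizes[a], sizes[b]
        merged = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        new_d2 = {}
        for c in clusters:
            nc = sizes[c]
            dac = d2[(min(a, c), max(a, c))]
            dbc = d2[(min(b, c), max(b, c))]
            dab = d2[(min(a, b), max(a, b))]
            new_d2[c] = ((na + nc) * dac + (nb + nc) * dbc - nc * dab) / \
                (na + nb + nc)
        d2 = {k: v for k, v in d2.items() if a not in k and b not in k}
        for c, v in new_d2.items():
            d2[(min(c, next_id), max(c, next_id))] = v
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        next_id += 1
    return {frozenset(c) for c in clusters.values()}


def jarvis_hull_area(points):
    """Gift-wrapping convex hull + shoelace, as an independent area oracle."""
    pts = [tuple(p) for p in points]
    start = min(pts)
    hull = [start]
    while True:
        cur = hull[-1]
        cand = pts[0] if pts[0] != cur else pts[1]
        for p in pts:
            if p == cur:
                continue
            cross = (cand[0] - cur[0]) * (p[1] - cur[1]) - \
                (cand[1] - cur[1]) * (p[0] - cur[0])
            if cross < 0 or (cross == 0 and
                             np.hypot(p[0] - cur[0], p[1] - cur[1]) >
                             np.hypot(cand[0] - cur[0], cand[1] - cur[1])):
                cand = p
        if cand == start:
            break
        hull.append(cand)
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def partition(assign):
    out = {}
    for i, lab in enumerate(assign.labels):
        if lab != -1:
            out.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in out.values()}


# ---------------------------------------------------------------------------


class TestEpsFromNnd:
    def test_zero_iqr(self):
        assert eps_from_nnd(np.array([10.0, 10, 10, 10])) == \
            pytest.approx(10.0, abs=1e-12)

    def test_quartile_convention(self):
        # median 30, Q1 20, Q3 40 under linear interpolation
        assert eps_from_nnd(np.array([10.0, 20, 30, 40, 50])) == \
            pytest.approx(60.0, abs=1e-12)

    @pytest.mark.parametrize("k", [0.1, 2.0, 1e3])
    def test_affine_equivariance(self, k, rng):
        v = rng.gamma(2, 15, 100)
        assert eps_from_nnd(v * k) == pytest.approx(k * eps_from_nnd(v),
                                                    rel=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            eps_from_nnd(np.array([1.0, 2, 3]))


class TestDbscan:
    def test_triangle_is_one_cluster(self):
        ps = ParticleSet([(0, 0), (20, 0), (10, 17.3)], channel="t")
        a = dbscan_clusters(ps, min_pts=3, eps=25.0)
        assert a.n_clusters == 1
        assert (a.labels >= 0).all()

    def test_pair_is_noise(self):
        ps = ParticleSet([(0, 0), (10, 0)], channel="t")
        a = dbscan_clusters(ps, min_pts=3, eps=25.0)
        assert a.n_clusters == 0
        assert (a.labels == -1).all()

    def test_mixed_scene_matches_reachability_oracle(self, rng):
        triad1 = np.array([(0, 0), (15, 0), (7, 12)], dtype=float)
        triad2 = triad1 + 500.0
        scatter = rng.uniform(1000, 3000, size=(5, 2))
        pts = np.vstack([triad1, triad2, scatter])
        ps = ParticleSet(pts, channel="t")
        a = dbscan_clusters(ps, min_pts=3, eps=25.0)
        assert a.n_clusters == 2
        assert (a.labels == -1).sum() == 5
        assert partition(a) == dbscan_oracle(pts, 25.0, 3)

    def test_random_patterns_match_oracle(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 400, size=(40, 2))
            eps = eps_from_nnd(
                np.sort(np.sqrt(((pts[:, None] - pts) ** 2).sum(-1)) +
                        np.eye(40) * 1e9, axis=1)[:, 0]
            )
            a = dbscan_clusters(ParticleSet(pts, channel="t"), 3, eps)
            assert partition(a) == dbscan_oracle(pts, eps, 3)

    def test_input_order_does_not_change_partition(self, rng):
        pts = rng.uniform(0, 300, size=(60, 2))
        a1 = dbscan_clusters(ParticleSet(pts, channel="t"), 3, 40.0)
        perm = rng.permutation(60)
        a2 = dbscan_clusters(ParticleSet(pts[perm], channel="t"), 3, 40.0)
        p1 = partition(a1)
        p2 = {frozenset(int(perm[i]) for i in c) for c in partition(a2)}
        assert p1 == p2

    def test_every_cluster_has_min_pts_members(self, rng):
        pts = rng.uniform(0, 500, size=(80, 2))
        a = dbscan_clusters(ParticleSet(pts, channel="t"), 3, 30.0)
        for cid in a.cluster_ids:
            assert (a.labels == cid).sum() >= 3
        assert (a.labels != -1).sum() + (a.labels == -1).sum() == 80


class TestWard:
    def test_single_point_is_singleton_cluster(self):
        a = ward_clusters(ParticleSet([(5, 5)], channel="t"))
        assert a.n_clusters == 1

    def test_two_distant_triads(self):
        triad = np.array([(0, 0), (10, 0), (5, 8)], dtype=float)
        ps = ParticleSet(np.vstack([triad, triad + 1000.0]), channel="t")
        assert ward_clusters(ps, cutoff=50.0).n_clusters == 2

    def test_matches_lance_williams_oracle(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 250, size=(25, 2))
            a = ward_clusters(ParticleSet(pts, channel="t"), cutoff=50.0)
            assert partition(a) == ward_lance_williams(pts, 50.0)


class TestHullArea:
    def test_right_triangle(self):
        area, degen = cluster_hull_area(np.array([(0, 0), (100, 0), (0, 100)]))
        assert area == pytest.approx(5000.0)
        assert not degen

    def test_square_side_30(self):
        area, _ = cluster_hull_area(
            np.array([(0, 0), (30, 0), (30, 30), (0, 30)])
        )
        assert area == pytest.approx(900.0)

    def test_collinear_members_flagged(self):
        area, degen = cluster_hull_area(np.array([(0, 0), (10, 10), (20, 20)]))
        assert area == 0.0 and degen

    def test_random_points_match_gift_wrapping_oracle(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 100, size=(20, 2))
            area, _ = cluster_hull_area(pts)
            assert area == pytest.approx(jarvis_hull_area(pts))


class TestSummaries:
    def test_single_cluster_numbers(self, square_um2):
        pts = np.array([(0, 0), (50, 0), (50, 20), (0, 20)], dtype=float) + 400
        ps = ParticleSet(pts, channel="t")
        a = dbscan_clusters(ps, 3, eps=60.0)
        summaries, density = summarize_clusters(a, square_um2)
        assert len(summaries) == 1
        s = summaries[0]
        assert s.n_particles == 4
        assert s.hull_area == pytest.approx(1000.0)
        assert s.intracluster_density == pytest.approx(0.004)
        assert density == pytest.approx(1.0)

    def test_no_clusters(self, square_um2):
        ps = ParticleSet([(100, 100), (900, 900)], channel="t")
        a = dbscan_clusters(ps, 3, eps=50.0)
        summaries, density = summarize_clusters(a, square_um2)
        assert summaries == [] and density == 0.0


class TestPsdFromMarker:
    def test_largest_cluster_wins(self, square_um2, rng):
        big = rng.uniform(0, 40, size=(10, 2)) + 200
        small = rng.uniform(0, 40, size=(4, 2)) + 700
        ps = ParticleSet(np.vstack([big, small]), channel="GluD2")
        psd = psd_from_marker(ps, square_um2)
        assert psd.kind == "PSD"
        c = psd.centroid
        assert 180 < c[0] < 260 and 180 < c[1] < 260

    def test_tie_broken_by_hull_area(self, square_um2):
        tight = np.array([(0, 0), (10, 0), (5, 8), (5, 3)], dtype=float) + 100
        wide = np.array([(0, 0), (40, 0), (20, 35), (20, 12)], dtype=float) + 700
        ps = ParticleSet(np.vstack([tight, wide]), channel="GluD2")
        psd = psd_from_marker(ps, square_um2, min_pts=3)
        assert psd.centroid[0] > 500

    def test_all_noise_raises(self, square_um2):
        pts = np.array([(0, 100), (300, 350), (600, 600), (900, 900)],
                       dtype=float)
        with pytest.raises(ValueError, match="PSD undefined"):
            psd_from_marker(ParticleSet(pts, channel="GluD2"), square_um2,
                            eps=50.0)
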