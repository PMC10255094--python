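import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp

from replipat import (
    GofResult,
    MaternParams,
    ParticleSet,
    RandomSimConfig,
    RimSpec,
    RoiPolygon,
    SceneSpec,
    compare_real_vs_sim_nnd,
    cpi_vs_random,
    displace_disk,
    fit_matern,
    gen_roi,
    ks_bootstrap_p,
    nnd_same,
    place_hardcore,
    sample_uniform_in_polygon,
    simulate_matern,
    simulate_random,
    subregion_density_vs_random,
)


class TestHardCorePlacement:
    def test_min_pairwise_distance_respected(self, square_um2, rng):
        for _ in range(10):
            pts = place_hardcore(square_um2, 60, 10.0, rng)
            assert pdist(pts).min() >= 10.0

    def test_infeasible_packing_raises(self):
        tiny = RoiPolygon(((0, 0), (30, 0), (30, 30), (0, 30)))
        with pytest.raises(ValueError, match="infeasible"):
            place_hardcore(tiny, 50, 10.0, np.random.default_rng(0),
                           max_attempts_per_point=200)

    def test_two_points_in_large_roi(self, square_um2, rng):
        pts = place_hardcore(square_um2, 2, 10.0, rng)
        assert np.hypot(*(pts[0] - pts[1])) >= 10.0


class TestDisplacement:
    def test_shift_magnitude_bounded_by_radius(self, rng):
        pts = np.zeros((5000, 2))
        shifted = displace_disk(pts, 30.0, rng)
        mags = np.hypot(shifted[:, 0], shifted[:, 1])
        assert mags.max() <= 15.0

    def test_mean_shift_is_two_thirds_radius(self, rng):
        # area-uniform displacement in a disk: E|shift| = (2/3) r_max
        pts = np.zeros((200_000, 2))
        mags = np.hypot(*displace_disk(pts, 30.0, rng).T)
        assert mags.mean() == pytest.approx(10.0, abs=0.05)

    def test_zero_diameter_is_identity(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        np.testing.assert_array_equal(displace_disk(pts, 0.0, rng), pts)

    def test_zero_displacement_stays_inside_roi(self, square_um2, rng):
        cfg = RandomSimConfig(displacement_diameter=0.0)
        ps = simulate_random(square_um2, 50, cfg, rng=rng)
        from replipat.geometry import _contains_mask

        assert _contains_mask(ps.points, square_um2, None).all()


class TestKsBootstrap:
    def test_small_sim_is_single_exact_test(self, rng):
        real = rng.gamma(2, 20, 500)
        sim = rng.gamma(2, 20, 80)
        assert ks_bootstrap_p(real, sim) == \
            pytest.approx(ks_2samp(np.sort(real), np.sort(sim)).pvalue)

    def test_order_invariance_and_reproducibility(self, rng):
        real = rng.gamma(2, 20, 400)
        sim = rng.gamma(2, 20, 400)
        p1 = ks_bootstrap_p(real, sim, n_rep=50, rng=np.random.default_rng(3))
        p2 = ks_bootstrap_p(real[::-1], rng.permutation(sim), n_rep=50,
                            rng=np.random.default_rng(3))
        assert p1 == p2

    def test_strongly_shifted_sample_rejected(self, rng):
        real = rng.normal(0, 1, 2000)
        sim = rng.normal(10, 1, 2000)
        assert ks_bootstrap_p(real, sim, n_rep=100, rng=rng) < 1e-6


class TestGofResult:
    @pytest.mark.parametrize(
        "p_apd,p_nnd,accepted",
        [(0.1, 0.1, True), (0.5, 0.09, False), (0.09, 0.5, False),
         (0.05, 0.05, False), (1.0, 1.0, True)],
    )
    def test_acceptance_is_conjunction_at_0_1(self, p_apd, p_nnd, accepted):
        assert GofResult(p_apd=p_apd, p_nnd=p_nnd).accepted is accepted


class TestMatern:
    def test_expected_count_matches_intensity(self, disk_4um2, rng):
        params = MaternParams(kappa=5.0, radius=20.0, mu=8.0)
        counts = [len(simulate_matern(params, disk_4um2, rng))
                  for _ in range(300)]
        expected = params.kappa * params.mu * 4.0  # per the 4 um^2 ROI
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_vanishing_mu_gives_mostly_empty_patterns(self, disk_4um2, rng):
        params = MaternParams(kappa=5.0, radius=20.0, mu=1e-4)
        counts = [len(simulate_matern(params, disk_4um2, rng))
                  for _ in range(50)]
        assert np.mean(counts) < 0.5

    def test_fit_intensity_identity(self, disk_4um2, rng):
        params = MaternParams(kappa=5.0, radius=20.0, mu=8.0)
        ps = simulate_matern(params, disk_4um2, rng)
        fit = fit_matern(ps, disk_4um2)
        n_implied = fit.kappa * 1e-6 * fit.mu * disk_4um2.area_nm2
        assert n_implied == pytest.approx(len(ps), rel=1e-6)

    def test_csr_input_flagged_degenerate(self, disk_4um2, rng):
        pts = sample_uniform_in_polygon(disk_4um2, 300, rng)
        fit = fit_matern(ParticleSet(pts, channel="t"), disk_4um2)
        assert fit.degenerate

    def test_coincident_points_rejected(self, disk_4um2):
        ps = ParticleSet(np.zeros((12, 2)) + 100.0, channel="t")
        with pytest.raises(ValueError):
            fit_matern(ps, disk_4um2)

    def test_large_radius_limit_indistinguishable_from_csr(self, disk_4um2, rng):
        # clusters as wide as the ROI lose their structure
        diam = 2 * np.sqrt(4e6 / np.pi)
        params = MaternParams(kappa=2.0, radius=diam, mu=40.0)
        ps = simulate_matern(params, disk_4um2, rng)
        csr = sample_uniform_in_polygon(disk_4um2, len(ps), rng)
        p = ks_2samp(nnd_same(ps).values,
                     nnd_same(ParticleSet(csr, channel="t")).values).pvalue
        assert p > 0.01


class TestComparisons:
    def test_clustered_real_nnd_below_random_null(self, rng):
        spec = SceneSpec(roi_area=2.0, seed=11)
        roi = gen_roi(spec)
        from replipat import gen_pattern

        ps, _ = gen_pattern(roi, spec)
        df = compare_real_vs_sim_nnd(ps, roi, "random", n_replicates=20,
                                     rng=rng)
        assert len(df) == 20
        assert (df.real_mean_nnd < df.sim_mean_nnd).mean() >= 0.95

    def test_csr_real_matches_unconstrained_null(self, square_um2, rng):
        pts = sample_uniform_in_polygon(square_um2, 100, rng)
        ps = ParticleSet(pts, channel="t")
        cfg = RandomSimConfig(min_distance=0.0, displacement_diameter=0.0)
        df = compare_real_vs_sim_nnd(ps, square_um2, "random", cfg,
                                     n_replicates=60, rng=rng)
        sims = df.sim_mean_nnd.to_numpy()
        # the real pattern is itself one CSR draw: compare at the
        # per-replicate spread
        assert abs(df.real_mean_nnd[0] - sims.mean()) < 4 * sims.std()

    def test_subregion_all_particles_in_az(self, rng):
        bouton = RoiPolygon(((0, 0), (2000, 0), (2000, 2000), (0, 2000)),
                            kind="bouton", id="bt")
        az = RoiPolygon(((800, 800), (1200, 800), (1200, 1200), (800, 1200)),
                        kind="AZ", id="az")
        pts = rng.uniform(810, 1190, size=(40, 2))
        ps = ParticleSet(pts, channel="t")
        df = subregion_density_vs_random(ps, bouton, az, n_replicates=20,
                                         rng=rng)
        assert (df.real_density > df.sim_density).all()

    def test_subregion_uniform_input_matches_null(self, rng):
        bouton = RoiPolygon(((0, 0), (2000, 0), (2000, 2000), (0, 2000)),
                            kind="bouton", id="bt")
        az = RoiPolygon(((500, 500), (1500, 500), (1500, 1500), (500, 1500)),
                        kind="AZ", id="az")
        pts = sample_uniform_in_polygon(bouton, 300, rng)
        ps = ParticleSet(pts, channel="t")
        df = subregion_density_vs_random(ps, bouton, az, n_replicates=100,
                                         rng=rng)
        sims = df.sim_density.to_numpy()
        assert abs(df.real_density[0] - sims.mean()) < 3 * sims.std()

    def test_subregion_az_enrichment_ratio_recovered(self, rng):
        # construction: AZ intensity twice the extra-AZ intensity
        bouton = RoiPolygon(((0, 0), (2000, 0), (2000, 2000), (0, 2000)),
                            kind="bouton", id="bt")
        az = RoiPolygon(((700, 700), (1300, 700), (1300, 1300), (700, 1300)),
                        kind="AZ", id="az")
        base = sample_uniform_in_polygon(bouton, 800, rng)
        extra = sample_uniform_in_polygon(az.polygon, 88, rng)
        ps = ParticleSet(np.vstack([base, extra]), channel="t")
        cfg = RandomSimConfig(min_distance=0.0, displacement_diameter=0.0)
        df = subregion_density_vs_random(ps, bouton, az, RimSpec(0), cfg,
                                         n_replicates=100, rng=rng)
        ratio = df.real_density[0] / df.sim_density.mean()
        # 800 uniform over 4 um^2 (200/um^2 everywhere) plus 88 extra in the
        # 0.36 um^2 AZ (+244/um^2): AZ density ~2x the pooled 888/4 um^2
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_subregion_outside_bouton_rejected(self, rng):
        bouton = RoiPolygon(((0, 0), (1000, 0), (1000, 1000), (0, 1000)),
                            kind="bouton")
        az = RoiPolygon(((900, 900), (1400, 900), (1400, 1400), (900, 1400)),
                        kind="AZ")
        ps = ParticleSet([(500, 500)], channel="t")
        with pytest.raises(ValueError):
            subregion_density_vs_random(ps, bouton, az, rng=rng)

    def test_cpi_uniform_input_matches_null(self, disk_4um2, rng):
        pts = sample_uniform_in_polygon(disk_4um2, 200, rng)
        real, sims = cpi_vs_random(ParticleSet(pts, channel="t"), disk_4um2,
                                   n_replicates=50, rng=rng)
        assert real == pytest.approx(0.5, abs=0.1)
        assert abs(real - sims.mean()) < 3 * sims.std()

    def test_cpi_edge_concentrated_exceeds_null(self, disk_4um2, rng):
        verts = np.asarray(disk_4um2.vertices)
        c = disk_4um2.centroid
        pts = c + 0.95 * (verts - c)
        real, sims = cpi_vs_random(ParticleSet(pts, channel="t"), disk_4um2,
                                   n_replicates=50, rng=rng)
        assert (real > sims).mean() >= 0.99

    def test_cpi_center_concentrated_below_null(self, disk_4um2, rng):
        c = disk_4um2.centroid
        pts = c + rng.normal(scale=30.0, size=(50, 2))
        real, sims = cpi_vs_random(ParticleSet(pts, channel="t"), disk_4um2,
                                   n_replicates=50, rng=rng)
        assert (real < sims).all()
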