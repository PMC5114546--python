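import numpy as np
import pytest
from scipy import stats

from pcnonp.sim_spatial import (
    GridConfig,
    TreePool,
    drop_mutation,
    genealogy_stream,
    null_trait_spatial,
    phi_to_lj,
    place_samples,
    risk_surface,
    simulate_genealogy,
    simulate_variants,
    window_mutation,
)


class TestPlacement:
    def test_one_per_square_bijection(self, rng):
        cfg = GridConfig(K0=4, n=16)
        phi = place_samples(GridConfig(K0=4, n=16, placement="one-per-square"), rng)
        assert sorted(phi) == list(range(16))

    def test_one_per_square_requires_matching_n(self, rng):
        with pytest.raises(ValueError):
            place_samples(GridConfig(K0=4, n=10, placement="one-per-square"), rng)

    def test_uniform_counts(self, rng):
        cfg = GridConfig(K0=5, n=10_000)
        phi = place_samples(cfg, rng)
        counts = np.bincount(phi, minlength=25)
        # multinomial: mean 400, sd ~ 19.6
        assert abs(counts - 400).max() < 5 * 19.6

    def test_support_and_coordinates(self, rng):
        cfg = GridConfig(K0=6, n=200)
        phi = place_samples(cfg, rng)
        assert phi.min() >= 0 and phi.max() < 36
        lj = phi_to_lj(phi, 6)
        assert lj.min() >= 1 and lj.max() <= 6


class TestGenealogy:
    def test_tree_is_binary_ultrametric(self, rng):
        cfg = GridConfig(K0=3, M=0.5, n=20)
        phi = place_samples(cfg, rng)
        tree = simulate_genealogy(phi, cfg, rng)
        assert tree.num_nodes == 2 * tree.num_leaves - 1
        leaves = tree.num_samples == 1
        assert np.allclose(tree.time[leaves], 0.0)
        internal = tree.time[~leaves]
        assert (internal > 0).all()
        # root subtends every leaf
        assert tree.num_samples.max() == tree.num_leaves
        # parent times strictly above child times
        has_parent = tree.parent >= 0
        assert (tree.time[tree.parent[has_parent]] >
                tree.time[has_parent.nonzero()[0]]).all()

    def test_single_deme_tmrca_matches_kingman(self, rng):
        """E[T_MRCA] for m lineages is 2(1 - 1/m) coalescent units."""
        cfg = GridConfig(K0=1, M=0.01, n=10)  # 20 lineages
        phi = place_samples(cfg, rng)
        times = [t.tmrca for t in genealogy_stream(phi, cfg, rng, total=1500)]
        expect = 2 * (1 - 1 / 20)
        assert np.mean(times) == pytest.approx(expect, rel=0.05)

    def test_isolated_corners_deepen_the_tree(self, rng):
        """Two diploids in opposite corners of a sparse grid coalesce
        far later than the panmictic expectation."""
        cfg = GridConfig(K0=10, M=0.001, n=2)
        phi = np.array([0, 99])
        times = [t.tmrca for t in genealogy_stream(phi, cfg, rng, total=30)]
        # panmictic E[T_MRCA] for 4 lineages is 1.5
        assert np.median(times) > 5 * 1.5


@pytest.fixture(scope="module")
def small_tree():
    rng = np.random.default_rng(7)
    cfg = GridConfig(K0=2, M=1.0, n=15)
    phi = place_samples(cfg, rng)
    return simulate_genealogy(phi, cfg, rng), cfg


class TestMutations:

    def test_genotypes_sum_to_carrier_count(self, small_tree, rng):
        tree, _ = small_tree
        g = drop_mutation(tree, rng)
        assert g.shape == (15,)
        assert set(np.unique(g)) <= {0, 1, 2}

    def test_singleton_window_gives_one_heterozygote(self, small_tree, rng):
        tree, _ = small_tree
        lo = 1 / tree.num_leaves
        g = window_mutation(tree, rng, (lo, lo + 1e-9))
        assert g.sum() == 1 and g.max() == 1

    def test_window_respected(self, small_tree, rng):
        tree, cfg = small_tree
        stream = genealogy_stream(place_samples(cfg, rng), cfg, rng, total=50)
        for _ in range(10):
            g = drop_mutation(tree, rng, maf_window=(0.1, 0.4), tree_source=stream)
            maf = min(g.sum(), 2 * 15 - g.sum()) / (2 * 15)
            assert 0.1 <= maf < 0.4

    def test_infeasible_window_errors(self, small_tree, rng):
        tree, _ = small_tree
        with pytest.raises(ValueError, match="window"):
            window_mutation(tree, rng, (0.0001, 0.001))

    def test_window_without_source_errors(self, small_tree, rng):
        tree, _ = small_tree
        with pytest.raises(ValueError, match="tree_source"):
            drop_mutation(tree, rng, maf_window=(0.1, 0.4))

    def test_panmictic_sfs_proportional_to_reciprocal(self, rng):
        """Derived-allele counts of random segregating sites follow the
        1/i neutral site-frequency spectrum."""
        cfg = GridConfig(K0=1, M=0.01, n=10)
        phi = place_samples(cfg, rng)
        # a random segregating site weights trees by total length; use
        # rejection (bound 30 >> E[L] ~ 7.1) for independent draws
        counts = []
        stream = genealogy_stream(phi, cfg, rng, total=60_000)
        for tree in stream:
            if rng.random() < tree.total_branch_length / 30.0:
                counts.append(int(drop_mutation(tree, rng).sum()))
            if len(counts) == 4000:
                break
        m = 2 * cfg.n
        observed = np.bincount(counts, minlength=m)[1:m]
        expected = (1 / np.arange(1, m)) / (1 / np.arange(1, m)).sum()
        chi2 = stats.chisquare(observed, expected * observed.sum())
        assert chi2.pvalue > 0.01

    def test_rare_variants_cluster_spatially(self, rng):
        """Carriers of rare variants sit closer together on the grid
        than carriers of common variants."""
        cfg = GridConfig(K0=10, M=0.01, n=100)
        phi = place_samples(cfg, rng)
        lj = phi_to_lj(phi, cfg.K0)
        dist_rare, dist_common = [], []
        for tree in genealogy_stream(phi, cfg, rng, total=400):
            g = drop_mutation(tree, rng)
            carriers = np.flatnonzero(g > 0)
            if carriers.size < 2:
                continue
            maf = min(g.sum(), 200 - g.sum()) / 200
            pts = lj[carriers]
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            mean_d = d[np.triu_indices(carriers.size, 1)].mean()
            if maf < 0.05:
                dist_rare.append(mean_d)
            elif maf > 0.2:
                dist_common.append(mean_d)
        assert np.mean(dist_rare) < np.mean(dist_common)

    def test_high_migration_washes_out_structure(self, rng):
        """With very large M the deme structure is invisible: folded
        MAF spectra match the single-deme coalescent."""
        n = 12
        maf_flat, maf_grid = [], []
        cfg1 = GridConfig(K0=1, M=0.01, n=n)
        cfg2 = GridConfig(K0=3, M=500.0, n=n)
        phi1 = place_samples(cfg1, rng)
        phi2 = place_samples(cfg2, rng)
        for tree in genealogy_stream(phi1, cfg1, rng, total=1200):
            s = drop_mutation(tree, rng).sum()
            maf_flat.append(min(s, 2 * n - s) / (2 * n))
        for tree in genealogy_stream(phi2, cfg2, rng, total=1200):
            s = drop_mutation(tree, rng).sum()
            maf_grid.append(min(s, 2 * n - s) / (2 * n))
        assert stats.ks_2samp(maf_flat, maf_grid).pvalue > 0.01


class TestRiskSurface:
    def test_model0_flat(self):
        assert risk_surface(0, 20).R.sum() == 0.0

    def test_model1_three_disjoint_blocks(self):
        R = risk_surface(1, 20).R
        assert set(np.unique(R)) == {0.0, 1.0}
        assert R.sum() == 48  # three disjoint 4x4 unit blocks
        # anchor (6,6): rows/cols 6..9 in 1-based coordinates
        assert R[5:9, 5:9].all()
        assert R[13:17, 5:9].all()
        assert R[13:17, 13:17].all()

    def test_model2_unit_peak_radially_decreasing(self):
        R = risk_surface(2, 20).R
        assert R[5, 5] == pytest.approx(1.0)
        row = R[5, 5:]
        assert (np.diff(row) <= 0).all()

    def test_unknown_model_errors(self):
        with pytest.raises(ValueError):
            risk_surface(3, 20)


class TestSpatialTrait:
    def test_model0_standard_normal(self, rng):
        cfg = GridConfig(K0=5, n=5000)
        phi = place_samples(cfg, rng)
        y = null_trait_spatial(phi, risk_surface(0, 5), cfg, rng)
        assert abs(y.mean()) < 3 / np.sqrt(5000)
        assert y.std() == pytest.approx(1.0, abs=0.05)

    def test_model1_block_shift_equals_beta(self, rng):
        cfg = GridConfig(K0=20, n=20_000, beta_risk=2.0)
        phi = place_samples(cfg, rng)
        surface = risk_surface(1, 20)
        y = null_trait_spatial(phi, surface, cfg, rng)
        inside = surface.at(phi) > 0
        diff = y[inside].mean() - y[~inside].mean()
        assert diff == pytest.approx(2.0, abs=0.1)


class TestVariantFactories:
    def test_simulate_variants_shape_and_window(self, rng):
        cfg = GridConfig(K0=3, M=0.5, n=30)
        phi = place_samples(cfg, rng)
        X = simulate_variants(phi, cfg, rng, 12, maf_window=(0.05, 0.5000001))
        assert X.shape == (30, 12)
        maf = np.minimum(X.sum(0), 60 - X.sum(0)) / 60
        assert (maf >= 0.05).all()

    def test_tree_pool_draws(self, rng):
        cfg = GridConfig(K0=3, M=0.5, n=25)
        phi = place_samples(cfg, rng)
        pool = TreePool(phi, cfg, rng, size=20)
        g = pool.draw_variants(rng, 5, (1 / 50, 0.5000001))
        assert g.shape == (25, 5)
        assert (g.sum(axis=0) > 0).all()
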