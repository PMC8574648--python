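import numpy as np
import pytest

import biclustbench as bb
from biclustbench.simulate import SIZE_FRACTIONS, _candidate_sizes


class TestPresets:
    def test_base_preset_matches_catalogue(self):
        c = bb.make_preset_config("base")
        assert (c.m, c.t, c.p, c.K) == (10, 10, 1000, 20)
        assert c.noise.family == "negbin" and c.noise.p_negbin == 0.3
        assert c.size_regime == "mixed"

    def test_large_k400_preset(self):
        c = bb.make_preset_config("Large-K400")
        assert (c.m, c.t, c.p, c.K) == (300, 20, 10000, 400)

    def test_gaussian_high_preset(self):
        c = bb.make_preset_config("Gaussian-high")
        assert c.noise.family == "gaussian" and c.noise.sigma == 300.0
        assert (c.m, c.t, c.p, c.K) == (10, 10, 1000, 20)

    @pytest.mark.parametrize(
        "name, field, value",
        [
            ("Negbin-high", "p_negbin", 0.01),
            ("Negbin-medium", "p_negbin", 0.1),
            ("Gaussian", "sigma", 20.0),
            ("Gaussian-medium", "sigma", 100.0),
        ],
    )
    def test_noise_variants(self, name, field, value):
        assert getattr(bb.make_preset_config(name).noise, field) == value

    def test_catalogue_has_all_named_datasets(self):
        names = set(bb.preset_names())
        assert len(names) == 28  # 24 base rows + 4 shift-scale variants
        assert {"base", "N50-T2", "Sparse-square", "K70", "shift-scale",
                "constant-samples"} <= names

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="base"):
            bb.make_preset_config("no-such-dataset")


class TestShapeSampling:
    def test_mixed_gene_candidates_p1000(self):
        assert _candidate_sizes(1000, SIZE_FRACTIONS["mixed"]) == [
            10, 100, 200, 500, 1000]

    def test_sparse_individual_candidates_m10_rounding(self):
        # 0.5 -> 0 -> floored to 1; 1.0 -> 1; 1.5 -> 2 (round-half-even)
        assert _candidate_sizes(10, SIZE_FRACTIONS["sparse"]) == [1, 1, 2]

    def test_dense_square_uses_one_fraction_for_both_axes(self, rng):
        config = bb.DatasetConfig(m=10, t=2, p=1000, K=1,
                                  size_regime="dense-square")
        for _ in range(20):
            spec = bb.sample_bicluster_shape(config, rng)
            assert spec.g_k / config.p == spec.m_k / config.m

    def test_blocks_are_contiguous_and_in_bounds(self, rng):
        config = bb.make_preset_config("base")
        for _ in range(50):
            spec = bb.sample_bicluster_shape(config, rng)
            assert 1 <= spec.t_k <= config.t
            assert 0 <= spec.gene_start <= config.p - spec.g_k
            assert 0 <= spec.individual_start <= config.m - spec.m_k
            assert 0 <= spec.tissue_start <= config.t - spec.t_k


class TestValueDistributions:
    def test_gamma_mean_parameters(self, rng):
        draws = bb.sample_bicluster_mean(2, 1 / 600, rng, size=200_000)
        assert draws.mean() == pytest.approx(1200, rel=0.02)
        assert draws.std() == pytest.approx(849, rel=0.03)

    def test_exponential_one_mean(self, rng):
        assert bb.sample_bicluster_mean(1, 1, rng, size=200_000).mean() == \
            pytest.approx(1.0, rel=0.02)

    def test_nonpositive_gamma_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            bb.sample_bicluster_mean(0, 1, rng)

    @pytest.mark.parametrize(
        "mu, p, expected",
        [(1200, 0.3, 1200 * 0.3 / 0.7), (0, 0.3, 0.0)],
    )
    def test_negbin_dispersion_formula(self, mu, p, expected):
        assert bb.negbin_dispersion(mu, p) == pytest.approx(expected)

    def test_negbin_dispersion_rejects_bad_p(self):
        with pytest.raises(ValueError):
            bb.negbin_dispersion(100, 1.0)

    def test_negbin_moments_match_construction(self, rng):
        n = bb.negbin_dispersion(1200, 0.3)
        draws = bb.sample_negbin(n, 0.3, 200_000, rng)
        assert draws.mean() == pytest.approx(1200, rel=0.01)
        # sd = sqrt(mu / p) = sqrt(4000) ~ 63.2
        assert draws.std() == pytest.approx(63.2, rel=0.03)

    def test_negbin_zero_dispersion_gives_zeros(self, rng):
        assert not bb.sample_negbin(0.0, 0.3, 100, rng).any()


class TestSimulateDataset:
    def test_base_shape_and_truth(self):
        ds = bb.simulate_dataset(bb.make_preset_config("base", seed=11))
        assert ds.Y.shape == (100, 1000)
        assert ds.truth.K == 20
        assert (ds.Y >= 0).all()
        assert np.array_equal(ds.Y, np.rint(ds.Y))  # counts are integers

    def test_identical_seed_bit_identical(self):
        a = bb.simulate_dataset(bb.make_preset_config("G100", seed=3))
        b = bb.simulate_dataset(bb.make_preset_config("G100", seed=3))
        assert np.array_equal(a.Y, b.Y) and a.truth == b.truth

    def test_distinct_seeds_distinct_draws(self):
        a = bb.simulate_dataset(bb.make_preset_config("G100", seed=3))
        b = bb.simulate_dataset(bb.make_preset_config("G100", seed=4))
        assert not np.array_equal(a.Y, b.Y)

    def test_background_only_mean(self):
        # K=0 leaves pure NegBin(1, 0.3) noise with mean (1-p)/p = 7/3
        config = bb.DatasetConfig(m=20, t=5, p=500, K=0, seed=5)
        ds = bb.simulate_dataset(config)
        assert ds.Y.mean() == pytest.approx(0.7 / 0.3, rel=0.02)

    def test_noiseless_full_bicluster_constant(self):
        config = bb.DatasetConfig(m=2, t=2, p=3, K=1, seed=9,
                                  noise=bb.NoiseSpec("none"))
        ds = bb.simulate_dataset(config)
        spec = ds.specs[0]
        inside = ds.Y[np.ix_(ds.truth[0].samples, ds.truth[0].genes)]
        assert np.allclose(inside, spec.mu_k)
        outside_mask = np.ones_like(ds.Y, dtype=bool)
        outside_mask[np.ix_(ds.truth[0].samples, ds.truth[0].genes)] = False
        assert np.all(ds.Y[outside_mask] == 0)

    def test_gaussian_dataset_clipped_nonnegative(self):
        ds = bb.simulate_dataset(bb.make_preset_config("Gaussian-high", seed=2))
        assert ds.Y.min() >= 0

    def test_truth_cells_inside_generated_blocks(self):
        ds = bb.simulate_dataset(bb.make_preset_config("G100", seed=13))
        for bcl, spec in zip(ds.truth, ds.specs):
            assert set(bcl.genes) == set(spec.genes)
            expected_samples = {
                l * ds.config.m + i
                for l in spec.tissues for i in spec.individuals
            }
            assert set(bcl.samples) == expected_samples
            assert bcl.n_cells == spec.m_k * spec.t_k * spec.g_k

    def test_bicluster_cell_mean_recovers_mu_plus_background(self):
        # mean inside a bicluster not overlapped by any other converges to
        # mu_k plus the background mean
        background = 0.7 / 0.3
        checked = 0
        for seed in range(5):
            config = bb.DatasetConfig(m=10, t=10, p=200, K=2, seed=seed)
            ds = bb.simulate_dataset(config)
            counts = ds.truth.coverage_counts()
            for bcl, spec in zip(ds.truth, ds.specs):
                cells = counts[np.ix_(bcl.samples, bcl.genes)]
                if bcl.n_cells >= 200 and (cells == 1).all():
                    inside = ds.Y[np.ix_(bcl.samples, bcl.genes)]
                    sem = np.sqrt(spec.mu_k / 0.3 / inside.size)
                    assert abs(inside.mean() - (spec.mu_k + background)) < \
                        3 * sem + 0.1 * background
                    checked += 1
        assert checked > 0, "no large non-overlapped bicluster in 5 seeds"

    def test_overlap_occurs_for_k20_presets(self):
        found = False
        for seed in range(10):
            ds = bb.simulate_dataset(bb.make_preset_config("base", seed=seed))
            if (ds.truth.coverage_counts() > 1).any():
                found = True
                break
        assert found, "no overlapping pair of truth biclusters in 10 seeds"


class TestFlattening:
    def test_row_order_is_tissue_major(self):
        tensor = np.arange(2 * 2 * 3).reshape(2, 2, 3)  # (m, t, p)
        Y, tissue_of, individual_of = bb.flatten_tensor(tensor)
        # expected order: (ind0,t0),(ind1,t0),(ind0,t1),(ind1,t1)
        assert np.array_equal(Y[0], tensor[0, 0])
        assert np.array_equal(Y[1], tensor[1, 0])
        assert np.array_equal(Y[2], tensor[0, 1])
        assert np.array_equal(Y[3], tensor[1, 1])
        assert list(tissue_of) == [0, 0, 1, 1]
        assert list(individual_of) == [0, 1, 0, 1]

    def test_maps_invert_sample_index(self):
        m, t = 10, 10
        tissue_of, individual_of = bb.sample_maps(m, t)
        assert len(tissue_of) == 100
        samples = tissue_of * m + individual_of
        assert np.array_equal(samples, np.arange(m * t))


class TestShiftScale:
    def test_constant_samples_constant_across_genes(self):
        config = bb.make_preset_config("constant-samples", seed=6)
        ds = bb.simulate_dataset(config)  # variant routed automatically
        for bcl, spec in zip(ds.truth, ds.specs):
            params = spec.shift_scale
            assert params.variant == "constant-samples"
            assert np.all(params.alpha == 1) and np.all(params.beta == 0)
        # pick a bicluster covered once: its rows are constant across genes
        counts = ds.truth.coverage_counts()
        for bcl in ds.truth:
            block = ds.Y[np.ix_(bcl.samples, bcl.genes)]
            if (counts[np.ix_(bcl.samples, bcl.genes)] == 1).all():
                assert np.allclose(block, block[:, :1])
                break

    def test_shift_variant_fixes_alpha(self):
        ds = bb.simulate_shift_scale_dataset(
            bb.make_preset_config("base", seed=1), "shift")
        assert all(np.all(s.shift_scale.alpha == 1) for s in ds.specs)

    def test_scale_variant_fixes_beta(self):
        ds = bb.simulate_shift_scale_dataset(
            bb.make_preset_config("base", seed=1), "scale")
        assert all(np.all(s.shift_scale.beta == 0) for s in ds.specs)

    def test_alpha_distribution_mean_one_mode_half(self, rng):
        draws = rng.exponential(0.5, size=200_000) + 0.5
        assert draws.mean() == pytest.approx(1.0, rel=0.02)
        assert draws.min() >= 0.5  # mode at the left edge 1/2

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            bb.simulate_shift_scale_dataset(
                bb.make_preset_config("base"), "rotate")

    def test_no_background_noise(self):
        ds = bb.simulate_shift_scale_dataset(
            bb.make_preset_config("base", seed=4), "shift-scale")
        outside = ds.truth.coverage_counts() == 0
        assert np.all(ds.Y[outside] == 0)


class TestKnockoutFixture:
    def test_design_arithmetic(self):
        fx = bb.simulate_knockout_fixture(5, 3, 2, 5, 20, seed=1)
        assert fx.n == 30 and fx.p == 100
        assert len(fx.genotype_traits) == 5
        assert all(len(t.samples) == 6 for t in fx.genotype_traits)
        assert len(fx.tissue_traits) == 3
        assert all(len(t.samples) == 10 for t in fx.tissue_traits)
        assert fx.truth.K == 5 + 3  # knockout + tissue biclusters

    def test_ideal_biclustering_scores_perfectly(self):
        fx = bb.simulate_knockout_fixture(5, 3, 2, 5, 20, seed=2)
        ideal = bb.ideal_knockout_biclustering(fx)
        score, detail = bb.knockout_biclustering_score(
            ideal, list(fx.genotype_traits), fx.knockout_pathways,
            fx.pathway_db, q_threshold=0.05)
        assert score == 1.0
        assert (detail["best_f1"] == 1.0).all()

    def test_zero_effect_mean_gives_pure_noise(self):
        fx = bb.simulate_knockout_fixture(
            4, 2, 2, 4, 10, effect_mean=0.0, tissue_effect_mean=0.0, seed=3)
        assert fx.Y.mean() == pytest.approx(0.7 / 0.3, rel=0.1)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            bb.simulate_knockout_fixture(0, 3, 2, 5, 20)
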