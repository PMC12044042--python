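import numpy as np
import pytest

from amyenc.data import AMY, AMY_SUBREGIONS
from amyenc.hrf import canonical_hrf, convolve_truncate
from amyenc.synthetic import (
    DEFAULT_RATING_COEFFS,
    REAL_REGION_SIZES,
    make_affective_imageset,
    make_cohort_ground_truth,
    make_feature_timeseries,
    make_ground_truth_weights,
    make_parcellation,
    make_toy_networks,
    session_features_from_networks,
    simulate_session,
)


class TestParcellation:
    def test_amy_is_union_of_subregions(self, small_parcellation):
        sizes = small_parcellation.region_sizes()
        assert sizes[AMY] == 10 + 5 + 5 + 4 == 24
        assert sizes[AMY] == sum(sizes[r] for r in AMY_SUBREGIONS)

    def test_real_scale_sizes(self):
        parc = make_parcellation(REAL_REGION_SIZES, seed=0)
        sizes = parc.region_sizes()
        for r in AMY_SUBREGIONS:
            assert 29 <= sizes[r] <= 178
        assert 247 <= sizes[AMY] <= 252

    def test_contiguous_ids_and_determinism(self):
        kw = dict(n_voxels_per_region={"LB": 4, "CM": 3, "VC": 5}, seed=9)
        p1, p2 = make_parcellation(**kw), make_parcellation(**kw)
        np.testing.assert_array_equal(p1.voxel_ids, np.arange(12))
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            make_parcellation({"LB": 0}, seed=0)

    def test_csv_roundtrip(self, small_parcellation, tmp_path):
        path = tmp_path / "parc.csv"
        small_parcellation.to_csv(path)
        from amyenc.data import Parcellation

        back = Parcellation.from_csv(path)
        np.testing.assert_array_equal(back.labels, small_parcellation.labels)


class TestFeatureTimeSeries:
    def test_rank_structure_without_noise(self):
        X = make_feature_timeseries(300, 50, 8, seed=7, noise_sd=0.0).data
        s = np.linalg.svd(X, compute_uv=False)
        assert s[8] < 1e-10 * s[7]

    def test_marginal_scale_stable_across_seeds(self):
        var = [
            make_feature_timeseries(200, 20, 5, seed=s).data.var(axis=0).mean()
            for s in range(20)
        ]
        assert max(var) / min(var) < 2.0

    def test_rank_validation(self):
        with pytest.raises(ValueError):
            make_feature_timeseries(100, 10, 11, seed=0)
        with pytest.raises(ValueError):
            make_feature_timeseries(5, 10, 8, seed=0)


class TestGroundTruth:
    def _mean_corrs(self, truth, parc):
        regions = parc.regions
        vecs = [truth.region_mean_weights(r) for r in regions]
        out = []
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                out.append(np.corrcoef(vecs[i], vecs[j])[0, 1])
        return np.array(out)

    def test_distinct_bases_nearly_orthogonal(self, small_parcellation):
        truth = make_ground_truth_weights(64, small_parcellation, 1.0, seed=3)
        assert (np.abs(self._mean_corrs(truth, small_parcellation)) < 0.2).all()

    def test_shared_base_highly_correlated(self, small_parcellation):
        truth = make_ground_truth_weights(64, small_parcellation, 0.0, seed=3)
        assert (self._mean_corrs(truth, small_parcellation) > 0.95).all()

    def test_deterministic(self, small_parcellation):
        a = make_ground_truth_weights(32, small_parcellation, 0.7, seed=11)
        b = make_ground_truth_weights(32, small_parcellation, 0.7, seed=11)
        np.testing.assert_array_equal(a.W, b.W)

    def test_cohort_shares_population_structure(self, small_parcellation):
        truths = make_cohort_ground_truth(
            48, small_parcellation, n_subjects=4, distinctness=1.0, seed=5
        )
        # the same region correlates strongly across subjects ...
        lb = [t.region_mean_weights("LB") for t in truths]
        for i in range(1, 4):
            assert np.corrcoef(lb[0], lb[i])[0, 1] > 0.8
        # ... while different regions stay dissimilar
        cm = truths[1].region_mean_weights("CM")
        assert abs(np.corrcoef(lb[0], cm)[0, 1]) < 0.4


class TestSimulateSession:
    def test_noiseless_forward_model_exact(self, small_parcellation, hrf_tr1):
        feats = make_feature_timeseries(120, 16, 4, seed=2)
        truth = make_ground_truth_weights(
            16, small_parcellation, 1.0, seed=2, noise_sd=0.0
        )
        bold = simulate_session(feats, truth, hrf_tr1, seed=0)
        expected = convolve_truncate(feats, hrf_tr1, 120).data @ truth.W
        assert np.abs(bold.data - expected).max() < 1e-10

    def test_pure_noise_has_unit_sd(self, small_parcellation, hrf_tr1):
        feats = make_feature_timeseries(1000, 8, 4, seed=4)
        truth = make_ground_truth_weights(
            8, small_parcellation, 1.0, seed=4, amplitude=0.0, noise_sd=1.0
        )
        bold = simulate_session(feats, truth, hrf_tr1, seed=1)
        sd = bold.data.std(axis=0, ddof=1)
        assert abs(sd.mean() - 1.0) < 0.1

    def test_seeded_determinism(self, small_parcellation, hrf_tr1):
        feats = make_feature_timeseries(100, 8, 4, seed=6)
        truth = make_ground_truth_weights(8, small_parcellation, 1.0, seed=6)
        a = simulate_session(feats, truth, hrf_tr1, seed=3)
        b = simulate_session(feats, truth, hrf_tr1, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_dimension_mismatch(self, small_parcellation, hrf_tr1):
        feats = make_feature_timeseries(100, 9, 4, seed=6)
        truth = make_ground_truth_weights(8, small_parcellation, 1.0, seed=6)
        with pytest.raises(ValueError):
            simulate_session(feats, truth, hrf_tr1, seed=0)


class TestAffectiveImageset:
    def test_ratings_standardized_exactly(self):
        _, ratings, _ = make_affective_imageset(60, seed=8, size=64)
        for dim in ("valence", "arousal"):
            v = ratings[dim].to_numpy()
            assert abs(v.mean()) < 1e-12
            assert abs(v.std(ddof=1) - 1.0) < 1e-12

    def test_zero_coefficients_uncorrelated_with_features(self):
        coeffs = {"valence": {}, "arousal": {}}
        _, ratings, feats = make_affective_imageset(
            400, coeffs=coeffs, noise_sd=1.0, seed=8, size=64
        )
        for col in ("median_r", "power_low", "power_high"):
            r = np.corrcoef(ratings["valence"], feats[col])[0, 1]
            assert abs(r) < 0.15

    def test_rating_model_fidelity(self):
        # regressing the returned (standardized) valence on the
        # standardized generating feature recovers the attenuated
        # coefficient c / sd(raw) within 3 standard errors
        c, noise = 0.5, 0.5
        coeffs = {"valence": {"power_low": c}, "arousal": {}}
        _, ratings, feats = make_affective_imageset(
            400, coeffs=coeffs, noise_sd=noise, seed=13, size=64
        )
        x = feats["power_low"].to_numpy()
        x = (x - x.mean()) / x.std(ddof=1)
        y = ratings["valence"].to_numpy()
        X = np.column_stack([np.ones(x.size), x])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        se = np.sqrt(res[0] / (x.size - 2) / (x**2).sum())
        expected = c / np.hypot(c, noise)
        assert abs(beta[1] - expected) < 3 * se

    def test_images_in_range_and_deterministic(self):
        imgs1, _, _ = make_affective_imageset(8, seed=4, size=32)
        imgs2, _, _ = make_affective_imageset(8, seed=4, size=32)
        assert imgs1.min() >= 0 and imgs1.max() <= 1
        np.testing.assert_array_equal(imgs1, imgs2)
        with pytest.raises(ValueError):
            make_affective_imageset(4, seed=0)


class TestToyNetworks:
    def test_zero_code_renders_mid_gray(self, toy_networks):
        img = toy_networks.generate(np.zeros(toy_networks.d_z))
        np.testing.assert_allclose(img, 0.5, atol=1e-12)

    def test_extractor_output_length(self, toy_networks, rng):
        img = rng.uniform(0, 1, size=(16, 16, 3))
        assert toy_networks.extract(img).shape == (12,)

    def test_composition_is_locally_continuous(self, toy_networks, rng):
        for _ in range(10):
            z = rng.standard_normal(toy_networks.d_z)
            f0 = toy_networks.features_from_code(z)
            for eps in (1e-3, 1e-5):
                delta = eps * rng.standard_normal(toy_networks.d_z)
                f1 = toy_networks.features_from_code(z + delta)
                assert np.linalg.norm(f1 - f0) < 100 * eps

    def test_reproducible_from_seed_and_roundtrip(self, tmp_path):
        a = make_toy_networks(4, 6, 8, 8, seed=2)
        b = make_toy_networks(4, 6, 8, 8, seed=2)
        np.testing.assert_array_equal(a.W_gen, b.W_gen)
        path = tmp_path / "net.npz"
        a.save(path)
        c = type(a).load(path)
        np.testing.assert_array_equal(a.W_ext, c.W_ext)

    def test_session_features_match_network_range(self, toy_networks):
        feats = session_features_from_networks(toy_networks, T=20, seed=1)
        assert feats.data.shape == (20, toy_networks.n_features)
        assert np.abs(feats.data).max() <= 1.0  # tanh range
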