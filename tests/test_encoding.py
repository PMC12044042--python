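import numpy as np
import pytest

from amyenc.data import AMY, AMY_SUBREGIONS, ParcellatedBOLD
from amyenc.encoding import (
    average_response_model,
    cross_validate,
    fisher_z,
    fit_encoding_model,
    group_voxel_inference,
    make_folds,
    subregion_contrast_suite,
)
from amyenc.hrf import convolve_truncate
from amyenc.pls import pls_predict
from amyenc.synthetic import (
    make_feature_timeseries,
    make_ground_truth_weights,
    make_parcellation,
    simulate_session,
)


@pytest.fixture(scope="module")
def noiseless_session(hrf_tr1_module=None):
    from amyenc.hrf import canonical_hrf

    hrf = canonical_hrf(dt=1.0)
    parc = make_parcellation({"LB": 6, "CM": 4, "SF": 4, "AStr": 3, "VC": 8}, seed=0)
    feats = make_feature_timeseries(150, 20, 6, seed=1)
    truth = make_ground_truth_weights(20, parc, 1.0, seed=1, noise_sd=0.0)
    bold = simulate_session(feats, truth, hrf, seed=0)
    conv = convolve_truncate(feats, hrf, 150)
    return conv, bold, truth


class TestFitEncodingModel:
    def test_noiseless_training_correlation_is_one(self, noiseless_session):
        conv, bold, _ = noiseless_session
        model = fit_encoding_model(conv, bold, AMY, n_components=20)
        pred = pls_predict(model.pls, conv.data)
        obs = bold.region_data(AMY)
        for v in range(obs.shape[1]):
            assert np.corrcoef(pred[:, v], obs[:, v])[0, 1] > 0.999

    def test_amy_pools_all_subregions(self, noiseless_session):
        conv, bold, _ = noiseless_session
        model = fit_encoding_model(conv, bold, AMY)
        assert model.n_voxels == 6 + 4 + 4 + 3
        sub_total = sum(
            fit_encoding_model(conv, bold, r).n_voxels for r in AMY_SUBREGIONS
        )
        assert model.n_voxels == sub_total

    def test_unknown_region_rejected(self, noiseless_session):
        conv, bold, _ = noiseless_session
        with pytest.raises(ValueError):
            fit_encoding_model(conv, bold, "THAL")


class TestCrossValidate:
    def test_fold_sizes(self):
        folds = make_folds(100, 5, seed=3)
        assert [f.size for f in folds] == [20] * 5
        assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(100))

    def test_high_snr_recovers_performance(self, noiseless_session):
        conv, bold, _ = noiseless_session
        perf = cross_validate(conv, bold, AMY, k=5, n_components=20, seed=2)
        assert perf.r.mean() > 0.95

    def test_shuffled_outcomes_destroy_performance(self, rng, noiseless_session):
        conv, bold, _ = noiseless_session
        shuffled = ParcellatedBOLD(
            data=bold.data[rng.permutation(bold.n_timepoints)],
            parcellation=bold.parcellation,
        )
        perf = cross_validate(conv, shuffled, AMY, k=5, n_components=10, seed=2)
        assert abs(perf.r.mean()) < 0.05

    def test_constant_voxel_gets_zero_r(self, noiseless_session):
        conv, bold, _ = noiseless_session
        data = bold.data.copy()
        data[:, 0] = 4.2
        flat = ParcellatedBOLD(data=data, parcellation=bold.parcellation)
        region0 = bold.parcellation.labels[0]
        perf = cross_validate(conv, flat, region0, k=5, n_components=5, seed=0)
        pos = np.flatnonzero(bold.parcellation.region_indices(region0) == 0)[0]
        assert perf.r[pos] == 0.0

    def test_seeded_determinism(self, noiseless_session):
        conv, bold, _ = noiseless_session
        a = cross_validate(conv, bold, "VC", k=5, n_components=5, seed=7)
        b = cross_validate(conv, bold, "VC", k=5, n_components=5, seed=7)
        np.testing.assert_array_equal(a.r, b.r)


class TestAverageResponseModel:
    def test_single_voxel_region_matches_cross_validate(self, noiseless_session):
        conv, bold, _ = noiseless_session
        parc = make_parcellation({"LB": 1}, seed=0)
        single = ParcellatedBOLD(data=bold.data[:, :1], parcellation=parc)
        a = cross_validate(conv, single, "LB", k=5, n_components=5, seed=4)
        b = average_response_model(conv, single, "LB", k=5, n_components=5, seed=4)
        assert a.r[0] == pytest.approx(b.r[0], abs=1e-12)

    def test_returns_single_pseudo_voxel(self, noiseless_session):
        conv, bold, _ = noiseless_session
        perf = average_response_model(conv, bold, AMY, seed=0)
        assert perf.r.shape == (1,)


class TestGroupVoxelInference:
    def test_all_zero_maps_nothing_significant(self):
        res = group_voxel_inference(np.zeros((5, 30)))
        assert not res["q_sig"].any()

    def test_matches_hand_step_up_rule(self, rng):
        # oracle: explicit Benjamini-Hochberg step-up applied to the
        # per-voxel t-test p-values computed independently here
        from scipy import stats

        Z = rng.standard_normal((8, 40))
        Z[:, :5] += 1.5
        res = group_voxel_inference(Z, q=0.05)
        t, p = stats.ttest_1samp(Z, 0.0, axis=0)
        np.testing.assert_allclose(res["p"], p, atol=1e-12)
        order = np.argsort(p)
        m = p.size
        below = np.flatnonzero(p[order] <= 0.05 * (np.arange(m) + 1) / m)
        expect = np.zeros(m, dtype=bool)
        if below.size:
            expect[order[: below.max() + 1]] = True
        np.testing.assert_array_equal(res["q_sig"].to_numpy(), expect)

    def test_missing_voxels_case_complete(self):
        Z = np.full((6, 4), 1.0)
        Z += 0.1 * np.arange(6)[:, None]
        Z[0, 2] = np.nan
        res = group_voxel_inference(Z)
        assert res["n"].tolist() == [6, 6, 5, 6]
        assert np.isfinite(res["t"]).all()

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            group_voxel_inference(np.zeros((1, 10)))


class TestFisherTransform:
    def test_odd_increasing_and_zero(self):
        r = np.linspace(-0.95, 0.95, 21)
        z = fisher_z(r)
        assert fisher_z(0.0) == 0.0
        np.testing.assert_allclose(fisher_z(-r), -z, atol=1e-12)
        assert (np.diff(z) > 0).all()


class TestSubregionContrasts:
    def test_identical_columns_give_null_results(self):
        data = np.tile(np.linspace(0.1, 0.5, 6)[:, None], (1, 4))
        res = subregion_contrast_suite(data)
        assert res.F == 0.0
        for c in res.contrasts:
            assert c.estimate == 0.0 and c.t == 0.0

    def test_constructed_sf_astr_effect(self, rng):
        base = 0.3 + 0.02 * rng.standard_normal((8, 4))
        delta = 0.1
        data = base.copy()
        data[:, 2] += delta
        data[:, 3] -= delta
        res = subregion_contrast_suite(data)
        third = res.contrasts[2]
        # weights (0, 0, +1, -1)/2 -> estimate 2*delta/2 = delta plus noise
        assert third.estimate == pytest.approx(delta, abs=0.02)
        assert third.t > 0

    def test_matches_statsmodels_anova_rm(self, rng):
        pd = pytest.importorskip("pandas")
        from statsmodels.stats.anova import AnovaRM

        data = rng.standard_normal((6, 4)) * 0.1 + 0.3
        res = subregion_contrast_suite(data)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 4),
                "region": np.tile(np.arange(4), 6),
                "z": data.ravel(),
            }
        )
        ref = AnovaRM(long, "z", "subject", within=["region"]).fit()
        assert res.F == pytest.approx(ref.anova_table["F Value"].iloc[0], rel=1e-8)
        assert res.p == pytest.approx(ref.anova_table["Pr > F"].iloc[0], rel=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            subregion_contrast_suite(np.zeros((2, 4)))
        bad = np.zeros((5, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            subregion_contrast_suite(bad)
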