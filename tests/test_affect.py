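import numpy as np
import pandas as pd
import pytest

from amyenc.affect import (
    DESIGN_COLUMNS,
    build_affect_design,
    compare_region_betas,
    group_affect_test,
    piecewise_valence_regression,
    predict_image_response,
    subject_affect_regression,
    valence_segment_mask,
)
from amyenc.data import AMY
from amyenc.encoding import fit_encoding_model
from amyenc.hrf import canonical_hrf, convolve_truncate
from amyenc.synthetic import (
    make_feature_timeseries,
    make_ground_truth_weights,
    make_parcellation,
    simulate_session,
)


def _toy_tables(rng, n=40):
    ids = np.arange(n)
    ratings = pd.DataFrame(
        {
            "image_id": ids,
            "valence": rng.standard_normal(n),
            "arousal": rng.standard_normal(n),
        }
    )
    feats = pd.DataFrame(
        {
            "image_id": ids,
            "median_r": rng.uniform(size=n),
            "median_g": rng.uniform(size=n),
            "median_b": rng.uniform(size=n),
            "power_low": rng.uniform(size=n),
            "power_high": rng.uniform(size=n),
        }
    )
    return ratings, feats


class TestBuildAffectDesign:
    def test_all_columns_standardized(self, rng):
        ratings, feats = _toy_tables(rng)
        design = build_affect_design(ratings, feats)
        assert list(design.columns) == ["image_id"] + DESIGN_COLUMNS
        for col in DESIGN_COLUMNS:
            v = design[col].to_numpy()
            assert abs(v.mean()) < 1e-8
            assert abs(v.std(ddof=1) - 1) < 1e-8

    def test_interaction_is_standardized_product(self, rng):
        ratings, feats = _toy_tables(rng)
        design = build_affect_design(ratings, feats)
        vz, az = design["valence_z"].to_numpy(), design["arousal_z"].to_numpy()
        prod = vz * az
        oracle = (prod - prod.mean()) / prod.std(ddof=1)
        np.testing.assert_allclose(design["interaction"], oracle, atol=1e-10)
        # product coding: congruent extremes are maximal pre-standardization
        i = np.argmax(vz * az)
        assert prod[i] == pytest.approx(vz[i] * az[i])

    def test_missing_ratings_dropped(self, rng):
        ratings, feats = _toy_tables(rng)
        ratings.loc[3, "valence"] = np.nan
        design = build_affect_design(ratings, feats)
        assert len(design) == len(ratings) - 1
        assert 3 not in design["image_id"].tolist()


@pytest.fixture(scope="module")
def model():
    hrf = canonical_hrf(dt=1.0)
    parc = make_parcellation({"LB": 4, "CM": 3, "SF": 3, "AStr": 2}, seed=0)
    feats = make_feature_timeseries(120, 10, 4, seed=2)
    truth = make_ground_truth_weights(10, parc, 1.0, seed=2, noise_sd=0.1)
    bold = simulate_session(feats, truth, hrf, seed=1)
    conv = convolve_truncate(feats, hrf, 120)
    return fit_encoding_model(conv, bold, AMY, n_components=8)


class TestPredictImageResponse:
    def test_mean_feature_returns_mean_response(self, model):
        vox, avg = predict_image_response(model, model.pls.x_mean)
        np.testing.assert_allclose(vox, model.pls.y_mean, atol=1e-10)
        assert avg == pytest.approx(model.pls.y_mean.mean())

    def test_linearity(self, model, rng):
        f1 = rng.standard_normal(10)
        f2 = rng.standard_normal(10)
        a = 0.3
        _, r1 = predict_image_response(model, f1)
        _, r2 = predict_image_response(model, f2)
        _, rmix = predict_image_response(model, a * f1 + (1 - a) * f2)
        assert rmix == pytest.approx(a * r1 + (1 - a) * r2)

    def test_batch_shape(self, model, rng):
        vox, avg = predict_image_response(model, rng.standard_normal((5, 10)))
        assert vox.shape == (5, model.n_voxels)
        assert avg.shape == (5,)


class TestSubjectRegression:
    def test_recovers_known_coefficient(self, rng):
        ratings, feats = _toy_tables(rng, n=300)
        design = build_affect_design(ratings, feats)
        y = 0.5 * design["valence_z"].to_numpy() + 0.01 * rng.standard_normal(300)
        sb = subject_affect_regression(y, design)
        assert sb.betas["valence_z"] == pytest.approx(0.5, abs=0.01)
        assert np.abs(sb.betas.drop("valence_z")).max() < 0.01

    def test_constant_outcome_gives_zero_betas(self, rng):
        ratings, feats = _toy_tables(rng)
        design = build_affect_design(ratings, feats)
        sb = subject_affect_regression(np.full(len(design), 2.0), design)
        assert np.abs(sb.betas).max() < 1e-10
        assert sb.intercept == pytest.approx(2.0)

    def test_matches_normal_equations(self, rng):
        ratings, feats = _toy_tables(rng, n=60)
        design = build_affect_design(ratings, feats)
        y = rng.standard_normal(60)
        sb = subject_affect_regression(y, design)
        X = np.column_stack(
            [np.ones(60), design[DESIGN_COLUMNS].to_numpy()]
        )
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(sb.betas.to_numpy(), oracle[1:], atol=1e-8)

    def test_collinear_design_names_columns(self, rng):
        ratings, feats = _toy_tables(rng)
        feats["power_low"] = feats["median_r"]
        design = build_affect_design(ratings, feats)
        with pytest.raises(ValueError, match="median_r"):
            subject_affect_regression(np.zeros(len(design)), design)


class TestGroupTests:
    def _betas(self, vals):
        return pd.DataFrame(
            {c: vals if c == "valence_z" else np.zeros(len(vals)) for c in DESIGN_COLUMNS},
            index=[f"sub-{i}" for i in range(len(vals))],
        )

    def test_zero_betas_give_zero_stats(self):
        res = group_affect_test(self._betas(np.zeros(5)))
        assert (res["t"] == 0).all() and (res["d"] == 0).all()

    def test_matches_hand_computed_t(self):
        vals = np.array([0.02, 0.05, -0.01, 0.03, 0.04])
        res = group_affect_test(self._betas(vals))
        t_hand = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        assert res.loc["valence_z", "t"] == pytest.approx(t_hand)
        assert res.loc["valence_z", "d"] == pytest.approx(
            vals.mean() / vals.std(ddof=1)
        )

    def test_effect_size_construction(self, rng):
        # d = mu / sigma by construction: 0.01 / 0.014 ~ 0.71
        vals = 0.01 + 0.014 * rng.standard_normal(4000)
        d = vals.mean() / vals.std(ddof=1)
        assert d == pytest.approx(0.01 / 0.014, abs=0.05)

    def test_compare_regions(self):
        A = self._betas(np.array([0.02, 0.05, -0.01, 0.03, 0.04]))
        same = compare_region_betas(A, A)
        assert (same["t"] == 0).all()
        B = A.copy()
        B["valence_z"] += 0.01
        res = compare_region_betas(A, B)
        assert res.loc["valence_z", "t"] < 0
        with pytest.raises(ValueError):
            compare_region_betas(A, B.iloc[::-1])


class TestPiecewiseValence:
    def test_segment_masks_overlap_as_defined(self):
        vz = np.array([-0.5, -1.5, 0.5, 1.5])
        assert valence_segment_mask(vz, "negative").tolist() == [True, True, False, False]
        assert valence_segment_mask(vz, "neutral").tolist() == [True, False, True, False]
        assert valence_segment_mask(vz, "positive").tolist() == [False, False, False, True]
        # z = -0.5 belongs to both the negative and the neutral segment
        assert valence_segment_mask(np.array([-0.5]), "negative")[0]
        assert valence_segment_mask(np.array([-0.5]), "neutral")[0]

    def test_v_shaped_response_splits_sign(self, rng):
        vz = rng.standard_normal(400)
        R = np.abs(vz)[None, :] + 0.1 * rng.standard_normal((12, 400))
        neg = piecewise_valence_regression(R, vz, "negative")
        pos = piecewise_valence_regression(R, vz, "positive")
        assert neg["mean_beta"] < 0 < pos["mean_beta"]

    def test_monotone_response_all_positive(self, rng):
        vz = rng.standard_normal(400)
        R = vz[None, :] + 0.1 * rng.standard_normal((12, 400))
        for seg in ("negative", "neutral", "positive"):
            assert piecewise_valence_regression(R, vz, seg)["mean_beta"] > 0

    def test_empty_segment_rejected(self):
        vz = np.array([-1.0, -2.0, -0.5] * 5)
        with pytest.raises(ValueError):
            piecewise_valence_regression(np.zeros((2, 15)), vz, "positive")
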