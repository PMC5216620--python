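import numpy as np
import pytest

from connage.errors import InsufficientDataError, UninformativeFeaturesError
from connage.prediction import (
    _uvpa_predictions,
    _uvpa_predictions_fast,
    consensus_features,
    mae,
    mvpa_nested_loocv,
    pearson_r,
    permutation_pvalue,
    rank_features_by_corr,
    uvpa_loocv,
)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([60.0, 65.0, 70.0])
        assert pearson_r(y, y) == pytest.approx(1.0)
        assert mae(y, y) == 0.0

    def test_constant_shift(self):
        y = np.array([60.0, 65.0, 70.0, 72.0])
        assert pearson_r(y + 1, y) == pytest.approx(1.0)
        assert mae(y + 1, y) == pytest.approx(1.0)

    def test_hand_mae(self):
        assert mae(np.array([60.0, 65.0]), np.array([62.0, 61.0])) == 3.0

    def test_zero_variance_sentinel(self):
        assert np.isnan(pearson_r(np.ones(4), np.array([1.0, 2, 3, 4])))

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            pearson_r(np.ones(2), np.ones(2))


class TestRankFeatures:
    def test_symmetric_pair_tie_by_index(self, rng):
        y = rng.normal(size=20)
        X = np.column_stack([y, rng.normal(size=20), -y])
        order = rank_features_by_corr(X, y)
        assert list(order[:2]) == [0, 2]  # both |r| = 1; index breaks the tie
        assert order[2] == 1

    def test_single_feature(self, rng):
        order = rank_features_by_corr(rng.normal(size=(10, 1)),
                                      rng.normal(size=10))
        assert list(order) == [0]

    def test_matches_bruteforce_sort(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        rs = [abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(5)]
        expected = sorted(range(5), key=lambda j: (-rs[j], j))
        assert list(rank_features_by_corr(X, y)) == expected

    def test_constant_feature_ranked_last(self, rng):
        y = rng.normal(size=15)
        X = np.column_stack([np.ones(15), y + rng.normal(0, 0.1, 15)])
        assert list(rank_features_by_corr(X, y)) == [1, 0]


class TestUVPA:
    def test_perfect_feature(self):
        ages = np.linspace(51, 76, 10)
        res = uvpa_loocv(ages.copy(), ages)
        np.testing.assert_allclose(res.predicted_ages, ages, atol=1e-8)
        assert res.r_pred_obs == pytest.approx(1.0)
        assert res.mae == pytest.approx(0.0, abs=1e-8)

    def test_hand_loocv_oracle_four_subjects(self):
        feat = np.array([1.0, 2.0, 3.0, 10.0])
        ages = np.array([55.0, 60.0, 65.0, 58.0])
        preds = _uvpa_predictions(feat, ages)
        for i in range(4):
            mask = np.arange(4) != i
            b, a = np.polyfit(feat[mask], ages[mask], 1)
            assert preds[i] == pytest.approx(a + b * feat[i], abs=1e-9)

    def test_fast_path_equals_explicit_loop(self, rng):
        for _ in range(20):
            feat = rng.normal(size=15)
            ages = rng.normal(60, 6, size=15)
            np.testing.assert_allclose(_uvpa_predictions_fast(feat, ages),
                                       _uvpa_predictions(feat, ages),
                                       atol=1e-10)

    def test_fast_path_constant_feature(self):
        ages = np.array([50.0, 60.0, 70.0, 80.0])
        np.testing.assert_allclose(_uvpa_predictions_fast(np.ones(4), ages),
                                   _uvpa_predictions(np.ones(4), ages))

    def test_null_feature_negative_r_in_expectation(self):
        # LOOCV on an uninformative feature is anti-correlated on average
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(200):
            ages = rng.uniform(51, 76, size=52)
            feat = rng.normal(size=52)
            preds = _uvpa_predictions_fast(feat, ages)
            r = np.corrcoef(preds, ages)[0, 1]
            if np.isfinite(r):
                rs.append(r)
        assert np.mean(rs) <= 0

    def test_minimum_subjects(self):
        with pytest.raises(InsufficientDataError):
            uvpa_loocv(np.ones(4), np.array([1.0, 2, 3, 4]))


class TestConsensus:
    def test_unanimous(self):
        assert consensus_features([(1, 2), (2, 1), (1, 2)]) == (1, 2)

    def test_threshold_three_of_four(self):
        sels = [(1,), (1,), (1,), (2,)]
        assert consensus_features(sels, theta=0.5) == (1,)
        assert consensus_features(sels, theta=1.0, fallback=9) == (9,)

    def test_total_disagreement_falls_back(self):
        sels = [(1,), (2,), (3,), (4,)]
        assert consensus_features(sels, theta=0.5, fallback=7) == (7,)

    def test_no_fallback_raises(self):
        with pytest.raises(UninformativeFeaturesError):
            consensus_features([(1,), (2,)], theta=1.0)


class TestMVPA:
    def test_single_feature_forced_selection(self, rng):
        ages = rng.uniform(51, 76, size=12)
        X = (ages + rng.normal(0, 2, 12))[:, None]
        res = mvpa_nested_loocv(X, ages)
        assert res.consensus_features == (0,)
        assert all(sel == (0,) for sel in res.per_fold_features)
        assert res.r_pred_obs > 0.5

    def test_planted_age_feature_recovered(self, rng):
        s, f_noise = 30, 20
        ages = rng.uniform(51, 76, size=s)
        X = np.column_stack([ages] + [rng.normal(size=s)
                                      for _ in range(f_noise)])
        res = mvpa_nested_loocv(X, ages)
        assert all(0 in sel for sel in res.per_fold_features)
        assert 0 in res.consensus_features
        assert res.r_pred_obs > 0.95

    def test_duplicate_informative_feature_harmless(self, rng):
        # duplicating a feature halves its effective ridge penalty, so exact
        # prediction equality only holds in the loss-dominated regime (large
        # C); there the duplicate is redundant and the tie rule puts both
        # copies first
        s = 16
        ages = rng.uniform(51, 76, size=s)
        signal = ages + rng.normal(0, 2, s)
        X_single = signal[:, None]
        X_dup = np.column_stack([signal, signal])
        res_single = mvpa_nested_loocv(X_single, ages, C=1000.0, tol=1e-9,
                                       max_sweeps=200000)
        res_dup = mvpa_nested_loocv(X_dup, ages, C=1000.0, tol=1e-9,
                                    max_sweeps=200000)
        np.testing.assert_allclose(res_dup.predicted_ages,
                                   res_single.predicted_ages, atol=1e-4)
        order = rank_features_by_corr(X_dup, ages)
        assert list(order) == [0, 1]

    def test_all_constant_features_rejected(self):
        with pytest.raises(UninformativeFeaturesError):
            mvpa_nested_loocv(np.ones((10, 3)), np.arange(10.0))

    def test_minimum_subjects(self, rng):
        with pytest.raises(InsufficientDataError):
            mvpa_nested_loocv(rng.normal(size=(6, 2)), np.arange(6.0))

    def test_determinism(self, rng):
        ages = rng.uniform(51, 76, size=12)
        X = np.column_stack([ages + rng.normal(0, 3, 12),
                             rng.normal(size=(12, 3))])
        a = mvpa_nested_loocv(X, ages, n_perm=5, rng_seed=3)
        b = mvpa_nested_loocv(X, ages, n_perm=5, rng_seed=3)
        np.testing.assert_array_equal(a.predicted_ages, b.predicted_ages)
        assert a.p_perm == b.p_perm
        assert a.per_fold_features == b.per_fold_features

    def test_feature_labels_reported(self, rng):
        ages = rng.uniform(51, 76, size=10)
        X = np.column_stack([ages, rng.normal(size=10)])
        res = mvpa_nested_loocv(X, ages, feature_labels=["sig", "noise"])
        assert "sig" in res.consensus_features


class TestPermutation:
    def test_extreme_case_plus_one_formula(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(51, 76, size=30)

        def predictor(_X, y):
            # perfect when y is in original order, terrible otherwise
            return 1.0 if np.array_equal(y, ages) else -1.0

        p = permutation_pvalue(predictor, None, ages, n_perm=1000, rng_seed=1)
        assert p == pytest.approx(1 / 1001)

    def test_single_losing_permutation(self):
        ages = np.array([1.0, 2.0, 3.0, 4.0, 5.0])

        def predictor(_X, y):
            return 1.0 if np.array_equal(y, ages) else 0.0

        assert permutation_pvalue(predictor, None, ages, n_perm=1,
                                  rng_seed=0) == 0.5

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            permutation_pvalue(lambda X, y: 0.0, None, np.arange(5.0),
                               n_perm=0)

    def test_bounds_respected(self, rng):
        ages = rng.uniform(51, 76, size=20)
        feat = rng.normal(size=20)
        res = uvpa_loocv(feat, ages, n_perm=99, rng_seed=5)
        assert 1 / 100 <= res.p_perm <= 1.0

    def test_uvpa_permutation_deterministic(self, rng):
        ages = rng.uniform(51, 76, size=20)
        feat = ages + rng.normal(0, 4, 20)
        a = uvpa_loocv(feat, ages, n_perm=49, rng_seed=9)
        b = uvpa_loocv(feat, ages, n_perm=49, rng_seed=9)
        assert a.p_perm == b.p_perm
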