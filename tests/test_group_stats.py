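import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connage.errors import EmptyFeatureError
from connage.group_stats import (
    DIR_DECREASE,
    DIR_INCREASE,
    FeatureDefinition,
    cluster_filter,
    define_features,
    extract_feature_table,
    fdr_bh,
    grid_adjacency,
    one_sample_t,
    residualize_covariates,
    two_sample_t,
    union_mask,
)
from connage.connectivity import ConnectivityMap


class TestOneSampleT:
    def test_all_zero_node_sentinel(self):
        res = one_sample_t(np.zeros((5, 2)))
        assert np.isnan(res.t_values).all()
        assert np.isnan(res.p_values).all()

    def test_zero_variance_positive_mean(self):
        z = np.ones((4, 1))
        res = one_sample_t(z)
        assert res.t_values[0] == np.inf
        assert res.p_values[0] == 0.0

    def test_matches_textbook_formula(self):
        z = np.array([2.0, -1.0, 0.5, 1.5, -0.5])[:, None]
        res = one_sample_t(z)
        expected = z.mean() / (z.std(ddof=1) / np.sqrt(5))
        assert res.t_values[0] == pytest.approx(expected, abs=1e-10)

    def test_nan_column_stays_sentinel(self, rng):
        z = rng.normal(size=(6, 2))
        z[:, 1] = np.nan
        res = one_sample_t(z)
        assert np.isfinite(res.t_values[0])
        assert np.isnan(res.t_values[1])


class TestResidualizeCovariates:
    def test_orthogonal_covariate_no_change(self, rng):
        z = rng.normal(size=(20, 3))
        z -= z.mean(axis=0)
        cov = rng.normal(size=20)
        cov -= cov.mean()
        # orthogonalize the covariate against every z column
        q, _ = np.linalg.qr(z)
        cov = cov - q @ (q.T @ cov)
        out = residualize_covariates(z, cov)
        np.testing.assert_allclose(out, z, atol=1e-8)

    def test_perfect_confound_removes_variance(self):
        cov = np.linspace(0, 1, 15)
        z = (3.0 * cov + 1.0)[:, None]
        out = residualize_covariates(z, cov)
        assert out[:, 0].std() < 1e-10
        assert out[:, 0].mean() == pytest.approx(z.mean(), abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        z = rng.normal(size=(8, 2))
        cov = rng.normal(size=(8, 2))
        design = np.hstack([np.ones((8, 1)), cov])
        beta = np.linalg.solve(design.T @ design, design.T @ z)
        expected = z - design @ beta + z.mean(axis=0)
        out = residualize_covariates(z, cov)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_group_means_preserved(self, rng):
        z = rng.normal(2.5, 1.0, size=(12, 4))
        out = residualize_covariates(z, rng.normal(size=(12, 2)))
        np.testing.assert_allclose(out.mean(axis=0), z.mean(axis=0),
                                   atol=1e-10)


class TestTwoSampleT:
    def test_identical_groups(self, rng):
        z = rng.normal(size=(5, 3))
        res = two_sample_t(z, z.copy())
        np.testing.assert_allclose(res.t_values, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.p_values, 1.0, atol=1e-12)

    def test_separated_zero_variance(self):
        zA = np.full((4, 1), 1.0)
        zB = np.full((4, 1), -1.0)
        res = two_sample_t(zA, zB)
        assert res.t_values[0] == np.inf
        assert res.p_values[0] == 0.0

    def test_matches_pooled_oracle(self, rng):
        zA = rng.normal(size=(5, 1))
        zB = rng.normal(size=(5, 1)) + 0.3
        res = two_sample_t(zA, zB)
        a, b = zA[:, 0], zB[:, 0]
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
            / (len(a) + len(b) - 2)
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res.t_values[0] == pytest.approx(expected, abs=1e-10)

    def test_mask_restricts_analysis(self, rng):
        zA = rng.normal(size=(5, 4))
        zB = rng.normal(size=(5, 4))
        res = two_sample_t(zA, zB, mask=np.array([True, False, True, False]))
        assert np.isfinite(res.t_values[0]) and np.isfinite(res.t_values[2])
        assert np.isnan(res.t_values[1]) and np.isnan(res.t_values[3])

    def test_empty_mask_warns(self, rng):
        zA = rng.normal(size=(4, 2))
        zB = rng.normal(size=(4, 2))
        with pytest.warns(RuntimeWarning):
            res = two_sample_t(zA, zB, mask=np.zeros(2, bool))
        assert np.isnan(res.t_values).all()


def _bh_bruteforce(p, q):
    """Largest BH rejection set by direct enumeration of step-up cutoffs."""
    p = np.asarray(p, float)
    m = len(p)
    best = np.zeros(m, bool)
    for k in range(m, 0, -1):
        kth = np.sort(p)[k - 1]
        if kth <= q * k / m:
            best = p <= kth
            break
    return best


class TestFdrBH:
    def test_hand_case(self):
        mask = fdr_bh(np.array([0.01, 0.02, 0.2, 0.9]), q=0.05)
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_all_ones_reject_none(self):
        assert not fdr_bh(np.ones(5)).any()

    def test_all_zero_reject_all(self):
        assert fdr_bh(np.zeros(5)).all()

    def test_nan_never_rejected(self):
        mask = fdr_bh(np.array([0.001, np.nan, 0.002]))
        np.testing.assert_array_equal(mask, [True, False, True])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    @settings(max_examples=200, deadline=None)
    def test_equals_bruteforce_enumeration(self, p, q):
        p = np.array(p)
        np.testing.assert_array_equal(fdr_bh(p, q=q), _bh_bruteforce(p, q))


class TestClusterFilter:
    def _chain_adjacency(self, n):
        adj = np.zeros((n, n), bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        return adj

    def test_small_component_removed_large_kept(self):
        n = 40
        adj = self._chain_adjacency(n)
        mask = np.zeros(n, bool)
        mask[:5] = True      # component of size 5
        adj[4, 5] = adj[5, 4] = False  # break the chain
        mask[6:37] = True    # component of size 31 > 23
        out = cluster_filter(mask, adj, k=23)
        assert not out[:5].any()
        assert out[6:37].all()

    def test_exactly_k_removed(self):
        adj = self._chain_adjacency(23)
        out = cluster_filter(np.ones(23, bool), adj, k=23)
        assert not out.any()

    def test_empty_mask(self):
        adj = self._chain_adjacency(5)
        assert not cluster_filter(np.zeros(5, bool), adj).any()

    def test_monotone_in_mask(self, rng):
        adj = grid_adjacency((4, 4, 2), connectivity=6)
        big = rng.random(32) < 0.7
        small = big & (rng.random(32) < 0.7)
        out_big = cluster_filter(big, adj, k=3)
        out_small = cluster_filter(small, adj, k=3)
        assert not np.any(out_small & ~out_big & ~small)
        # shrinking input never grows output
        assert out_small.sum() <= out_big.sum() or not np.any(out_small & ~out_big)

    def test_grid_adjacency_face_counts(self):
        adj = grid_adjacency((3, 3, 3), connectivity=6)
        center = np.ravel_multi_index((1, 1, 1), (3, 3, 3))
        assert adj[center].sum() == 6
        corner = np.ravel_multi_index((0, 0, 0), (3, 3, 3))
        assert adj[corner].sum() == 3


class TestFeatures:
    def _diff(self, t, mask):
        from connage.group_stats import GroupStatResult

        t = np.asarray(t, float)
        mask = np.asarray(mask, bool)
        direction = np.where(mask, np.sign(t), 0).astype(int)
        return GroupStatResult(t, np.where(mask, 0.01, 0.5), mask, mask,
                               direction)

    def test_roi_mode_one_feature_per_node(self):
        labels = ["a", "b", "c"]
        diff = self._diff([2.0, -3.0, 0.5], [True, True, False])
        feats = define_features(diff, "seedX", labels)
        assert {(f.label, f.direction) for f in feats} == {
            ("a and seedX", DIR_INCREASE), ("b and seedX", DIR_DECREASE)}

    def test_no_difference_empty_list(self):
        diff = self._diff([0.1, 0.2], [False, False])
        assert define_features(diff, "s", ["a", "b"]) == []

    def test_single_node_feature_value_equals_node_z(self, rng):
        z = rng.normal(size=3)
        cmap = ConnectivityMap("s1", "seedX", ["a", "b", "c"],
                               r_values=np.tanh(z), z_values=z)
        fd = FeatureDefinition("b and seedX", "seedX", (1,), DIR_INCREASE)
        table = extract_feature_table({"s1": {"seedX": cmap}}, [fd])
        assert table.values[0, 0] == pytest.approx(z[1])

    def test_component_feature_is_mean_z(self, rng):
        z = rng.normal(size=4)
        cmap = ConnectivityMap("s1", "seedX", list("abcd"),
                               r_values=np.tanh(z), z_values=z)
        fd = FeatureDefinition("ab and seedX", "seedX", (0, 2), DIR_DECREASE)
        table = extract_feature_table({"s1": {"seedX": cmap}}, [fd])
        assert table.values[0, 0] == pytest.approx(z[[0, 2]].mean())

    def test_empty_feature_list_raises(self):
        with pytest.raises(EmptyFeatureError):
            extract_feature_table({}, [])

    def test_grid_mode_components_merge(self):
        labels = [f"v{i}" for i in range(5)]
        adj = np.zeros((5, 5), bool)
        adj[0, 1] = adj[1, 0] = True
        diff = self._diff([2.0, 2.5, 0, 0, -1.5], [True, True, False, False,
                                                   True])
        feats = define_features(diff, "s", labels, adjacency=adj)
        assert {f.label for f in feats} == {"v0+v1 and s", "v4 and s"}


class TestNullErrorControl:
    def test_global_null_rejection_rate(self):
        # no effects anywhere: fraction of replicates with any BH rejection
        # stays near q (it equals FWER under the global null)
        rng = np.random.default_rng(42)
        n_rej = 0
        reps = 200
        for _ in range(reps):
            zA = rng.normal(size=(20, 100)) * 0.064
            zB = rng.normal(size=(20, 100)) * 0.064
            res = two_sample_t(zA, zB)
            if res.fdr_mask.any():
                n_rej += 1
        assert n_rej / reps <= 0.07


class TestDirectionRecovery:
    def test_generator_effects_recovered(self, small_cohort, small_config):
        from connage.connectivity import rsfc_map, seed_from_labels
        from connage.synthetic import INSULA_NODES, PARIETAL_NODES

        records, series, _, _ = small_cohort
        labels = small_config.node_labels
        seeds = ["M1.L", "S1.R"]
        is_older = np.array([r.group == "older" for r in records])
        for lab in seeds:
            rows = [rsfc_map(series[r.subject_id],
                             seed_from_labels(lab, labels)).z_values
                    for r in records]
            z = np.vstack(rows)
            diff = two_sample_t(z[is_older], z[~is_older])
            for node in INSULA_NODES:
                assert diff.t_values[labels.index(node)] < 0
            for node in PARIETAL_NODES:
                assert diff.t_values[labels.index(node)] > 0


class TestUnionMask:
    def test_union_of_cluster_masks(self, rng):
        a = one_sample_t(rng.normal(0.5, 0.1, size=(10, 3)))
        b = one_sample_t(rng.normal(0.0, 0.1, size=(10, 3)))
        m = union_mask(a, b)
        np.testing.assert_array_equal(m, a.cluster_mask | b.cluster_mask)
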