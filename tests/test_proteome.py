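"""Differential proteomics: filtering, normalization, moderated t, volcano, QC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atriomics import (SimStudyConfig, VolcanoConfig, cluster_for_heatmap,
                       filter_missing, list_overlap, moderated_t,
                       normalize_matrix, pca_variance, permutation_volcano,
                       sample_correlation, simulate_proteomics)
from conftest import make_matrix


class TestFilterMissing:
    def test_three_of_six_missing_removed_two_retained(self):
        values = [[1, 2, 3, 4, 5, 6],
                  [1, np.nan, np.nan, np.nan, 5, 6],   # 3 missing -> removed
                  [1, np.nan, np.nan, 4, 5, 6]]        # 2 missing -> retained
        m = make_matrix(values)
        out = filter_missing(m, max_missing=2)
        assert list(out.feature_ids) == ["F0", "F2"]

    def test_identity_when_no_feature_exceeds(self):
        m = make_matrix([[1, 2, 3, 4, 5, 6], [7, 8, 9, 1, 2, 3]])
        out = filter_missing(m, max_missing=5)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent_and_order_preserving(self):
        values = np.arange(60, dtype=float).reshape(10, 6) + 1
        values[::3, 0] = np.nan
        values[::3, 1] = np.nan
        values[::3, 2] = np.nan
        m = make_matrix(values)
        once = filter_missing(m, 2)
        twice = filter_missing(once, 2)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert list(once.feature_ids) == [f for f in m.feature_ids
                                          if f in set(once.feature_ids)]

    def test_max_missing_must_be_below_sample_count(self):
        m = make_matrix([[1, 2, 3, 4, 5, 6]])
        with pytest.raises(ValueError):
            filter_missing(m, max_missing=6)


class TestNormalizeMatrix:
    def test_two_point_row_closed_form(self):
        m = make_matrix([[2.0, 8.0]])
        out = normalize_matrix(m, log_base2=True, zscore=True)
        # log2 -> (1, 3); sample-SD z-score -> (-1/sqrt2, +1/sqrt2)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   [[-0.70710678, 0.70710678]])

    def test_constant_row_emitted_as_zero_with_warning(self):
        m = make_matrix([[8.0, 8.0, 8.0, 8.0]])
        with pytest.warns(UserWarning, match="zero-SD"):
            out = normalize_matrix(m)
        np.testing.assert_array_equal(out.values.to_numpy(), [[0, 0, 0, 0]])

    def test_identity_when_both_flags_false(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0]])
        out = normalize_matrix(m, log_base2=False, zscore=False)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_nonpositive_value_under_log_names_offender(self):
        m = make_matrix([[1.0, -2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="F0"):
            normalize_matrix(m)

    def test_missing_entries_stay_missing(self):
        m = make_matrix([[2.0, np.nan, 8.0, 4.0]])
        out = normalize_matrix(m)
        assert out.missing_mask.to_numpy().sum() == 1
        assert bool(out.values.isna().iloc[0, 1])


class TestModeratedT:
    def test_s0_zero_reduces_to_student_t(self, rng):
        m = make_matrix(rng.normal(10, 1, size=(20, 6)))
        res = moderated_t(m, s0=0.0)
        np.testing.assert_allclose(res["d_mod"], res["t_raw"])
        # cross-check p against scipy
        a, b = m.group_columns()
        sp = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=1)
        np.testing.assert_allclose(res["p_raw"], sp.pvalue, rtol=1e-10)

    def test_identical_groups_give_zero_t_unit_p(self):
        m = make_matrix([[3.0, 4.0, 5.0, 3.0, 4.0, 5.0]])
        res = moderated_t(m, s0=0.1)
        assert res["t_raw"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == 1.0

    def test_beta_galactosidase_replicates_give_published_p(self):
        # AF vs sham activity replicates; pooled two-sided p rounds to 0.60
        m = make_matrix([[2.64, 3.02, 3.26, 2.48, 2.57, 5.68]])
        res = moderated_t(m, s0=0.0)
        assert round(float(res["p_raw"].iloc[0]), 2) == 0.60

    def test_insufficient_group_coverage_flagged(self):
        m = make_matrix([[1.0, np.nan, np.nan, 4.0, 5.0, 6.0]])
        res = moderated_t(m)
        assert math.isnan(res["t_raw"].iloc[0])
        assert "fewer than 2" in res["reason"].iloc[0]


def _brute_force_volcano(values, n1, s0, fdr_target):
    """Independent oracle: explicit loops over all balanced splits."""
    n_feat, m = values.shape

    def d_stat(cols_a, cols_b):
        out = np.empty(n_feat)
        for i in range(n_feat):
            a = [values[i, j] for j in cols_a if not math.isnan(values[i, j])]
            b = [values[i, j] for j in cols_b if not math.isnan(values[i, j])]
            if len(a) < 2 or len(b) < 2:
                out[i] = math.nan
                continue
            ma, mb = sum(a) / len(a), sum(b) / len(b)
            va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
            vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
            sp = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
            se = math.sqrt(sp * (1 / len(a) + 1 / len(b)))
            out[i] = (ma - mb) / (se + s0) if (se + s0) > 0 else math.inf
        return out

    splits = list(itertools.combinations(range(m), n1))
    obs = np.abs(d_stat(list(range(n1)), list(range(n1, m))))
    perms = [np.abs(d_stat(list(s), [j for j in range(m) if j not in s]))
             for s in splits]
    cutoffs = sorted(set(x for x in obs if math.isfinite(x)))
    best_cut = None
    running_min = math.inf
    for c in cutoffs:
        obs_hits = sum(1 for x in obs if not math.isnan(x) and x >= c)
        false = sorted(sum(1 for x in p if not math.isnan(x) and x >= c)
                       for p in perms)
        k = len(false)
        med = (false[k // 2] if k % 2 else
               0.5 * (false[k // 2 - 1] + false[k // 2]))
        fdr = med / max(1, obs_hits)
        running_min = min(running_min, fdr)
        if running_min <= fdr_target and best_cut is None:
            best_cut = c
    if best_cut is None:
        return np.zeros(n_feat, dtype=bool)
    return np.array([not math.isnan(x) and x >= best_cut for x in obs])


class TestPermutationVolcano:
    def test_exhaustive_mode_equals_brute_force_oracle(self):
        cfg = SimStudyConfig(seed=21, n_features=50, frac_regulated=0.2,
                             effect_log2=2.0, missing_rate=0.1,
                             missing_mode="random", sigma_range=(0.2, 0.5))
        matrix, _ = simulate_proteomics(cfg)
        matrix = normalize_matrix(filter_missing(matrix, 2), zscore=False)
        res = permutation_volcano(matrix, VolcanoConfig())
        assert res.attrs["exhaustive"]
        assert res.attrs["n_permutations_used"] == 20
        expected = _brute_force_volcano(matrix.values.to_numpy(), 3,
                                        s0=0.1, fdr_target=0.05)
        np.testing.assert_array_equal(res["significant"].to_numpy(), expected)

    def test_null_data_flags_nothing_substantial(self):
        cfg = SimStudyConfig(seed=22, n_features=300, frac_regulated=0.0)
        matrix, _ = simulate_proteomics(cfg)
        res = permutation_volcano(normalize_matrix(matrix, zscore=False),
                                  VolcanoConfig())
        assert res["significant"].mean() <= 0.02

    def test_one_separated_feature_is_flagged_up(self, rng):
        values = rng.normal(20, 0.3, size=(40, 6))
        values[0, :3] += 8.0          # AF columns strongly up
        res = permutation_volcano(make_matrix(values), VolcanoConfig())
        assert bool(res["significant"].iloc[0])
        assert res["direction"].iloc[0] == "up"
        assert (res["direction"][res["significant"]] != "ns").all()

    def test_sign_consistency_between_fc_and_dmod(self, rng):
        values = rng.normal(20, 1, size=(50, 6))
        res = permutation_volcano(make_matrix(values), VolcanoConfig())
        ok = res["d_mod"].notna() & (res["log2_fc"] != 0)
        assert (np.sign(res.loc[ok, "log2_fc"])
                == np.sign(res.loc[ok, "d_mod"])).all()


class TestPCA:
    def test_fractions_match_covariance_eigenvalues(self, rng):
        m = make_matrix(rng.normal(size=(3, 4)))
        _, fractions = pca_variance(m)
        X = m.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        eig = eig[:len(fractions)]
        np.testing.assert_allclose(fractions, eig / eig.sum(), atol=1e-8)

    def test_fractions_sorted_and_sum_to_one(self, rng):
        m = make_matrix(rng.normal(size=(30, 6)))
        scores, fractions = pca_variance(m)
        assert np.all(np.diff(fractions) <= 1e-12)
        assert np.isclose(fractions.sum(), 1.0)
        assert scores.shape[0] == 6

    def test_missing_values_rejected(self):
        m = make_matrix([[1.0, np.nan, 3.0, 4.0]])
        with pytest.raises(ValueError, match="filter"):
            pca_variance(m)

    def test_zero_variance_matrix_warns(self):
        m = make_matrix(np.ones((5, 4)))
        with pytest.warns(UserWarning, match="zero-variance"):
            _, fractions = pca_variance(m)
        assert np.isnan(fractions).all()


class TestSampleCorrelation:
    def test_unit_diagonal_and_antithetic_pair(self):
        x = np.array([1.0, 2.0, 5.0, 3.0, 4.0])
        values = np.column_stack([x, -x, x + 1, 2 * x])
        m = make_matrix(values)
        corr = sample_correlation(m)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)
        assert corr.iloc[0, 2] == pytest.approx(1.0)

    def test_five_point_pair_matches_hand_formula(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 3.0, 1.0, 7.0, 6.0])
        m = make_matrix(np.column_stack([x, y, x, y]))
        corr = sample_correlation(m)
        xc, yc = x - x.mean(), y - y.mean()
        rho = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        assert corr.iloc[0, 1] == pytest.approx(rho, abs=1e-12)


class TestClustering:
    def test_two_separated_blobs_recovered_perfectly(self, rng):
        blob1 = rng.normal(0, 0.1, size=(10, 6))
        blob2 = rng.normal(10, 0.1, size=(10, 6))
        m = make_matrix(np.vstack([blob1, blob2]))
        labels, row_order, col_order = cluster_for_heatmap(m, k=2, seed=0)
        from sklearn.metrics import adjusted_rand_score
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        assert sorted(row_order) == list(range(20))
        assert sorted(col_order) == list(range(6))

    def test_k_one_single_label(self, rng):
        m = make_matrix(rng.normal(size=(5, 4)))
        labels, _, _ = cluster_for_heatmap(m, k=1)
        assert set(labels) == {0}

    def test_duplicated_rows_share_cluster(self, rng):
        row = rng.normal(size=6)
        values = np.vstack([row, row, row + 20, row + 20])
        labels, _, _ = cluster_for_heatmap(make_matrix(values), k=2)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]

    def test_k_above_feature_count_rejected(self, rng):
        m = make_matrix(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            cluster_for_heatmap(m, k=5)


class TestListOverlap:
    @pytest.mark.parametrize("a, b, expected_pct", [
        ({1, 2, 3}, {1, 2, 3}, 100.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2, 3}, {2, 3, 4, 5}, 40.0),
    ])
    def test_shared_fraction_of_union(self, a, b, expected_pct):
        out = list_overlap(a, b)
        assert out["shared_pct"] == pytest.approx(expected_pct)

    def test_counts(self):
        out = list_overlap({1, 2, 3}, {2, 3, 4, 5})
        assert (out["n_shared"], out["n_a_only"], out["n_b_only"]) == (2, 1, 2)

    def test_both_empty_undefined(self):
        with pytest.warns(UserWarning):
            out = list_overlap(set(), set())
        assert math.isnan(out["shared_pct"])
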