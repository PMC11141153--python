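"""Integrated enrichment: VST, harmonization, ranking rules, joint test, q-values."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atriomics import (OmicsMatrix, SimStudyConfig, category_scores,
                       classify_tiers, detect_outlier_samples, gene_t_stats,
                       harmonize_ids, manova_enrichment_test, qvalues,
                       rank_datasets, simulate_study, vst_transform)
from atriomics.enrichment import EXCLUDED, RANKED, RANKED_LAST, RankProfile
from conftest import make_matrix


class TestVST:
    def test_c_zero_equals_log2(self):
        m = make_matrix([[4.0, 8.0, 16.0, 2.0]])
        out = vst_transform(m, c=0.0, calibrate=False)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   np.log2(m.values.to_numpy()))

    def test_glog_at_zero_closed_form(self):
        m = make_matrix([[0.0, 8.0, 16.0, 2.0]])
        out = vst_transform(m, c=4.0, calibrate=False)
        assert out.values.iloc[0, 0] == pytest.approx(math.log2(4.0 / 2.0))

    def test_variance_stabilization_on_heteroscedastic_input(self, rng):
        # variance proportional to mean^2 at low intensity: raw log2 explodes
        # for small x; glog should flatten the row-SD vs row-mean trend
        n = 400
        base = np.exp2(rng.uniform(2, 12, size=n))
        values = base[:, None] + rng.normal(0, 30.0, size=(n, 6))
        values = np.clip(values, 0.01, None)
        m = make_matrix(values)
        raw_log = np.log2(values)
        out = vst_transform(m, calibrate=False).values.to_numpy()

        def slope(mat):
            mu = mat.mean(axis=1)
            sd = mat.std(axis=1, ddof=1)
            return np.polyfit(mu, sd, 1)[0]

        assert abs(slope(out)) < abs(slope(raw_log))

    def test_all_missing_sample_rejected(self):
        m = make_matrix([[np.nan, 1.0, 2.0, 3.0], [np.nan, 4.0, 5.0, 6.0]])
        with pytest.raises(ValueError, match="all-missing"):
            vst_transform(m)


class TestHarmonizeIDs:
    def test_identity_map_leaves_matrices_unchanged(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]])
        out, = harmonize_ids([m], {"F0": ["F0"], "F1": ["F1"]})
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_many_to_one_median_collapse(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0],
                         [3.0, 6.0, 5.0, 8.0],
                         [9.0, 9.0, 9.0, 9.0]])
        idmap = {"F0": ["H1"], "F1": ["H1"], "F2": ["H2"]}
        out, = harmonize_ids([m], idmap, collapse="median")
        np.testing.assert_allclose(out.values.loc["H1"], [2.0, 4.0, 4.0, 6.0])
        np.testing.assert_allclose(out.values.loc["H2"], [9.0] * 4)

    def test_max_abs_collapse_picks_extreme_per_cell(self):
        m = make_matrix([[1.0, -5.0, 3.0, 4.0], [-2.0, 4.0, -1.0, 8.0]])
        out, = harmonize_ids([m], {"F0": ["H"], "F1": ["H"]},
                             collapse="max_abs")
        np.testing.assert_allclose(out.values.loc["H"], [-2.0, -5.0, 3.0, 8.0])

    def test_collision_counting(self, rng):
        n = 40
        values = rng.normal(size=(n, 4))
        m = make_matrix(values)
        # 10 collisions: F0..F9 -> shared targets pairwise
        idmap = {f"F{i}": [f"H{i // 2}" if i < 20 else f"H{i}"]
                 for i in range(n)}
        out, = harmonize_ids([m], idmap)
        assert out.n_features == n - 10

    def test_unmapped_features_dropped_and_empty_map_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]])
        out, = harmonize_ids([m], {"F0": ["H0"]})
        assert list(out.feature_ids) == ["H0"]
        with pytest.raises(ValueError, match="covered"):
            harmonize_ids([m], {"X": ["Y"]})


class TestOutlierDetection:
    def test_identical_samples_flag_nothing(self):
        m = make_matrix(np.tile([[1.0, 1, 1, 1, 1, 1]], (10, 1)))
        assert detect_outlier_samples([m], threshold_mad=5.0) == []

    def test_planted_outlier_flagged(self, rng):
        values = rng.normal(10, 0.5, size=(50, 6))
        values[:, 2] *= 10.0        # third AF sample wildly shifted
        m = make_matrix(values)
        assert detect_outlier_samples([m], threshold_mad=5.0) == ["AF3"]

    def test_infinite_threshold_flags_nothing(self, rng):
        m = make_matrix(rng.normal(size=(30, 6)))
        assert detect_outlier_samples([m], threshold_mad=math.inf) == []

    def test_removal_below_two_per_group_aborts(self, rng):
        values = rng.normal(0, 0.01, size=(40, 6))
        values[:, 3] += 50.0
        values[:, 4] -= 50.0        # two of three sham samples far out
        m = make_matrix(values)
        with pytest.raises(ValueError, match="aborted"):
            detect_outlier_samples([m], threshold_mad=3.0)


class TestGeneTStats:
    def test_matches_hand_computed_pooled_t(self):
        a, b = [4.1, 5.2, 3.9], [2.0, 2.5, 2.2]
        m = make_matrix([a + b])
        t = gene_t_stats(m)
        expected = stats.ttest_ind(a, b).statistic
        assert t.iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_identical_groups_zero(self):
        m = make_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        assert gene_t_stats(m).iloc[0] == 0.0

    def test_zero_variance_shift_gives_signed_infinity(self):
        m = make_matrix([[5.0, 5.0, 5.0, 2.0, 2.0, 2.0]])
        assert gene_t_stats(m).iloc[0] == math.inf
        m2 = make_matrix([[2.0, 2.0, 2.0, 5.0, 5.0, 5.0]])
        assert gene_t_stats(m2).iloc[0] == -math.inf


class TestRankDatasets:
    def test_plain_midrank_when_no_missing(self):
        tstats = {"TL": pd.Series({"g1": -1.0, "g2": 0.5, "g3": 0.5,
                                   "g4": 2.0})}
        profile = rank_datasets(tstats)
        assert profile.ranks["TL"] == {"g1": 1.0, "g2": 2.5, "g3": 2.5,
                                       "g4": 4.0}
        assert all(s == RANKED for s in profile.status["TL"].values())

    def test_gene_missing_in_one_proteomics_dataset_ranked_last(self):
        tstats = {
            "TL": pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0}),
            "EL": pd.Series({"g1": 1.0, "g2": 2.0, "g3": np.nan}),
        }
        profile = rank_datasets(tstats)
        assert profile.status["EL"]["g3"] == RANKED_LAST
        # bottom block of one gene sits at rank 3 of an EL universe of 3
        assert profile.ranks["EL"]["g3"] == 3.0
        assert profile.status["TL"]["g3"] == RANKED

    def test_ranked_last_block_shares_midrank(self):
        tstats = {
            "TL": pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 4.0}),
            "EL": pd.Series({"g1": 1.0, "g2": 2.0, "g3": np.nan,
                             "g4": np.nan}),
        }
        profile = rank_datasets(tstats)
        # two ranked-last genes share mid-rank of positions 3 and 4
        assert profile.ranks["EL"]["g3"] == 3.5
        assert profile.ranks["EL"]["g4"] == 3.5
        # rank sum preserved: 1 + 2 + 3.5 + 3.5 = n(n+1)/2 for n=4
        assert sum(profile.ranks["EL"].values()) == 10.0

    def test_transcript_only_gene_excluded_from_proteomics(self):
        tstats = {
            "TL": pd.Series({"g1": 1.0, "g2": 2.0, "g3": np.nan}),
            "EL": pd.Series({"g1": 0.5, "g2": 1.5, "g3": np.nan}),
            "RNA": pd.Series({"g1": 0.1, "g2": 0.2, "g3": 0.3}),
        }
        profile = rank_datasets(tstats)
        assert profile.status["TL"]["g3"] == EXCLUDED
        assert profile.status["EL"]["g3"] == EXCLUDED
        assert "g3" not in profile.ranks["TL"]
        assert profile.status["RNA"]["g3"] == RANKED

    def test_rna_missing_gene_not_ranked_last_in_rna(self):
        tstats = {
            "TL": pd.Series({"g1": 1.0, "g2": 2.0}),
            "RNA": pd.Series({"g1": 0.1, "g2": np.nan}),
        }
        profile = rank_datasets(tstats)
        assert "g2" not in profile.ranks["RNA"]


class TestCategoryScores:
    def test_full_universe_scores_zero_everywhere(self):
        tstats = {"TL": pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)]),
                  "EL": pd.Series(np.arange(10.0)[::-1], index=[f"g{i}" for i in range(10)])}
        profile = rank_datasets(tstats)
        scores = category_scores(profile, [f"g{i}" for i in range(10)])
        assert scores["TL"] == pytest.approx(0.0)
        assert scores["EL"] == pytest.approx(0.0)

    def test_top_k_closed_form(self):
        n, k = 100, 2
        tstats = {"TL": pd.Series(np.arange(float(n)),
                                  index=[f"g{i}" for i in range(n)])}
        profile = rank_datasets(tstats)
        scores = category_scores(profile, ["g98", "g99"])   # the top 2 ranks
        assert scores["TL"] == pytest.approx((2 / 100) * (99.5 - 50.5))
        assert scores["TL"] == pytest.approx(0.98)

    def test_reversing_ranks_flips_sign(self, rng):
        n = 30
        t = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        members = [f"g{i}" for i in range(5)]
        s_fwd = category_scores(rank_datasets({"TL": t}), members)
        s_rev = category_scores(rank_datasets({"TL": -t}), members)
        assert s_fwd["TL"] == pytest.approx(-s_rev["TL"])


class TestManovaEnrichment:
    def test_one_dimension_reduces_to_normal_rank_sum(self, rng):
        n, k = 50, 8
        t = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        members = [f"g{i}" for i in rng.choice(n, k, replace=False)]
        profile = rank_datasets({"TL": t})
        t2, p, _ = manova_enrichment_test(profile, members)
        ranks = stats.rankdata(t.to_numpy())
        mean_rank = np.mean([ranks[int(g[1:])] for g in members])
        z = (mean_rank - (n + 1) / 2) / math.sqrt((n - k) * (n + 1) / (12 * k))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-9)

    def test_small_instance_matches_permutation_oracle(self, rng):
        # two correlated datasets, n = 12 genes, category size 3
        n, k = 12, 3
        base = rng.normal(size=n)
        t1 = pd.Series(base + rng.normal(0, 0.5, n),
                       index=[f"g{i}" for i in range(n)])
        t2_ = pd.Series(base + rng.normal(0, 0.5, n),
                        index=[f"g{i}" for i in range(n)])
        profile = rank_datasets({"TL": t1, "EL": t2_})
        members = ["g0", "g5", "g11"]
        T2_obs, p_obs, _ = manova_enrichment_test(profile, members, min_per_side=2)

        draws = 4000
        hits = 0
        ids = np.array([f"g{i}" for i in range(n)])
        for _ in range(draws):
            random_members = ids[rng.choice(n, k, replace=False)]
            T2_r, _, _ = manova_enrichment_test(profile, random_members,
                                                min_per_side=2)
            if T2_r >= T2_obs:
                hits += 1
        p_perm = hits / draws
        mc_err = math.sqrt(max(p_perm, 1 / draws) * (1 - p_perm) / draws)
        assert abs(p_obs - p_perm) < max(3 * mc_err, 0.035)

    def test_membership_floor_skips_pathway(self):
        t = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        profile = rank_datasets({"TL": t})
        t2, p, ks = manova_enrichment_test(profile, ["g0"], min_per_side=2)
        assert math.isnan(p) and ks == {}

    def test_invariant_under_monotone_transform_of_t(self, rng):
        n = 40
        t = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        members = [f"g{i}" for i in range(6)]
        p1 = manova_enrichment_test(rank_datasets({"TL": t}), members)[1]
        p2 = manova_enrichment_test(rank_datasets({"TL": np.tanh(t) * 7 + 3}),
                                    members)[1]
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestQValues:
    def test_hand_bh_example(self):
        q = qvalues([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_single_p(self):
        np.testing.assert_allclose(qvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(qvalues([0.2]), [0.2])

    def test_monotone_and_at_least_p(self, rng):
        p = rng.uniform(size=200)
        q = qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_reapplication_never_increases_significance(self, rng):
        # already-corrected values cannot become more significant again
        p = rng.uniform(size=100)
        q = qvalues(p)
        assert (qvalues(q) >= q - 1e-12).all()
        np.testing.assert_allclose(qvalues(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])

    def test_storey_variant_no_larger_than_bh(self, rng):
        p = np.concatenate([rng.uniform(0, 0.01, 20), rng.uniform(size=80)])
        assert (qvalues(p, "storey") <= qvalues(p, "bh") + 1e-12).all()


class TestTiers:
    @pytest.mark.parametrize("q, sig, tier", [
        (0.5, False, "non_confident"),
        (0.005, True, "confident"),
        (1e-5, True, "highly_confident"),
        (0.01, False, "non_confident"),      # boundary: q < 0.01 strict
    ])
    def test_tier_mapping(self, q, sig, tier):
        significant, tiers = classify_tiers(np.array([q]))
        assert bool(significant[0]) is sig
        assert tiers[0] == tier
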