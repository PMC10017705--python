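"""Spearman cohort correlations, common/random pooling, groups, tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import watlas as w
from watlas.clinical_meta import (cluster_association_profiles,
                                  cohort_correlations, group_comparisons,
                                  meta_analyze, pool_correlations)

from conftest import mannwhitney_u_oracle, spearman_oracle


def _cohort(n, rho, rng, celltype="T0", trait="homa"):
    cov = [[1, rho], [rho, 1]]
    x = rng.multivariate_normal([0, 0], cov, size=n)
    scores = pd.DataFrame({celltype: x[:, 0]},
                          index=[f"s{i}" for i in range(n)])
    traits = pd.DataFrame({trait: x[:, 1]}, index=scores.index)
    return scores, traits


class TestCohortCorrelations:
    def test_monotone_trait_gives_rho_one(self):
        scores = pd.DataFrame({"T0": [1.0, 2.0, 5.0, 9.0, 12.0]},
                              index=list("abcde"))
        traits = pd.DataFrame({"bmi": [0.1, 0.4, 0.5, 2.0, 7.0]},
                              index=list("abcde"))
        out = cohort_correlations(scores, traits)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_independent_trait_near_zero(self):
        rng = np.random.default_rng(0)
        scores, traits = _cohort(500, 0.0, rng)
        out = cohort_correlations(scores, traits)
        assert abs(out.loc[0, "rho"]) < 0.1

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        y = rng.normal(size=8) + 0.5 * x
        scores = pd.DataFrame({"T0": x}, index=[f"s{i}" for i in range(8)])
        traits = pd.DataFrame({"tg": y}, index=scores.index)
        out = cohort_correlations(scores, traits)
        assert out.loc[0, "rho"] == pytest.approx(spearman_oracle(x, y),
                                                  abs=1e-10)

    def test_missing_values_pairwise_complete(self):
        scores = pd.DataFrame({"T0": [1.0, 2, 3, 4, 5, 6]},
                              index=list("abcdef"))
        traits = pd.DataFrame({"t": [1.0, 2, 3, np.nan, 5, 6]},
                              index=list("abcdef"))
        out = cohort_correlations(scores, traits)
        assert out.loc[0, "n"] == 5
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_small_or_constant_combinations_flagged(self):
        scores = pd.DataFrame({"T0": [1.0, 2, 3, 4]}, index=list("abcd"))
        traits = pd.DataFrame({"const": [2.0, 2, 2, 2],
                               "short": [1.0, 2, np.nan, np.nan]},
                              index=list("abcd"))
        out = cohort_correlations(scores, traits).set_index("trait")
        assert out.loc["const", "flag"] == "constant"
        assert out.loc["short", "flag"] == "n<4"
        assert np.isnan(out.loc["const", "rho"])

    def test_trait_sign_flip_flips_rho(self):
        rng = np.random.default_rng(2)
        scores, traits = _cohort(60, 0.5, rng)
        r1 = cohort_correlations(scores, traits).loc[0, "rho"]
        r2 = cohort_correlations(scores, -traits).loc[0, "rho"]
        assert r1 == pytest.approx(-r2, abs=1e-12)


class TestPoolCorrelations:
    def test_single_cohort_fixed_equals_random(self):
        mc = pool_correlations([(0.4, 53)])
        assert mc.fixed == pytest.approx(mc.random)
        assert mc.tau2 == 0.0
        z = np.arctanh(0.4)
        se = 1 / np.sqrt(50)
        assert mc.fixed[1] == pytest.approx(np.tanh(z - 1.959964 * se),
                                            abs=1e-6)

    def test_identical_cohorts_no_heterogeneity(self):
        mc = pool_correlations([(0.3, 60)] * 5)
        assert mc.fixed[0] == pytest.approx(0.3, abs=1e-12)
        assert mc.q == pytest.approx(0.0, abs=1e-12)
        assert mc.tau2 == 0.0
        assert mc.random == pytest.approx(mc.fixed)

    def test_fixed_variance_never_exceeds_single_cohort(self):
        cohorts = [(0.2, 30), (0.5, 80), (0.35, 50)]
        mc = pool_correlations(cohorts)
        pooled_halfwidth = np.arctanh(mc.fixed[2]) - np.arctanh(mc.fixed[0])
        for rho, n in cohorts:
            assert pooled_halfwidth <= 1.959964 / np.sqrt(n - 3) + 1e-12

    def test_heterogeneous_cohorts_widen_random_ci(self):
        mc = pool_correlations([(0.8, 100), (-0.2, 100), (0.5, 100)])
        assert mc.tau2 > 0
        fixed_w = mc.fixed[2] - mc.fixed[1]
        rand_w = mc.random[2] - mc.random[1]
        assert rand_w > fixed_w

    def test_perfect_correlation_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            mc = pool_correlations([(1.0, 20), (0.5, 30)])
        assert np.isfinite(mc.fixed[0])

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="n=3"):
            pool_correlations([(0.2, 3)])

    def test_dersimonian_laird_matches_hand_formula(self):
        cohorts = [(0.6, 40), (0.1, 90), (0.35, 25)]
        z = np.arctanh([r for r, _ in cohorts])
        v = 1.0 / (np.array([n for _, n in cohorts]) - 3.0)
        wts = 1.0 / v
        zf = (wts * z).sum() / wts.sum()
        q = (wts * (z - zf) ** 2).sum()
        tau2 = max(0.0, (q - 2) / (wts.sum() - (wts ** 2).sum() / wts.sum()))
        wr = 1.0 / (v + tau2)
        zr = (wr * z).sum() / wr.sum()
        mc = pool_correlations(cohorts)
        assert mc.tau2 == pytest.approx(tau2, abs=1e-12)
        assert mc.q == pytest.approx(q, abs=1e-12)
        assert mc.random[0] == pytest.approx(np.tanh(zr), abs=1e-12)

    def test_recovery_and_coverage_over_replicates(self):
        """8 homogeneous cohorts at true Spearman 0.4: fixed estimate lands
        within 0.05 of truth and the 95% CI covers it ~95% of the time."""
        rng = np.random.default_rng(1234)
        r_pearson = 2 * np.sin(np.pi * 0.4 / 6)  # population Spearman 0.4
        covered, estimates = 0, []
        n_reps = 200
        for _ in range(n_reps):
            per = []
            for _ in range(8):
                n = int(rng.integers(50, 151))
                x = rng.multivariate_normal(
                    [0, 0], [[1, r_pearson], [r_pearson, 1]], size=n)
                per.append((stats.spearmanr(x[:, 0], x[:, 1]).statistic, n))
            mc = pool_correlations(per)
            estimates.append(mc.fixed[0])
            covered += mc.fixed[1] <= 0.4 <= mc.fixed[2]
        assert abs(np.mean(estimates) - 0.4) < 0.05
        assert 0.90 <= covered / n_reps <= 0.99


class TestMetaAnalyze:
    def test_pools_across_cohort_tables(self):
        rng = np.random.default_rng(5)
        tables = []
        for _ in range(4):
            scores, traits = _cohort(80, 0.5, rng)
            tables.append(cohort_correlations(scores, traits))
        out = meta_analyze(tables)
        assert out.loc[0, "k"] == 4
        assert 0.2 < out.loc[0, "rho_fixed"] < 0.75

    def test_flagged_cohorts_dropped_not_pooled(self):
        good = pd.DataFrame([{"celltype": "T0", "trait": "t", "rho": 0.5,
                              "n": 40, "flag": "ok"}])
        bad = pd.DataFrame([{"celltype": "T0", "trait": "t", "rho": np.nan,
                             "n": 2, "flag": "n<4"}])
        out = meta_analyze([good, bad])
        assert out.loc[0, "k"] == 1


class TestAssociationClustering:
    def test_planted_anticorrelated_blocks_split(self):
        rng = np.random.default_rng(6)
        pos = np.tile([0.5, 0.4, 0.45], (4, 1))
        neg = -pos
        noise = rng.normal(0, 0.05, size=(5, 3))
        mat = pd.DataFrame(
            np.vstack([pos + rng.normal(0, 0.03, pos.shape),
                       neg + rng.normal(0, 0.03, neg.shape),
                       noise]),
            index=[f"ct{i}" for i in range(13)],
            columns=["homa", "tg", "leptin"])
        groups = cluster_association_profiles(mat, n_groups=3)
        pos_groups = groups.iloc[:4]
        neg_groups = groups.iloc[4:8]
        assert pos_groups.nunique() == 1
        assert neg_groups.nunique() == 1
        assert pos_groups.iloc[0] != neg_groups.iloc[0]
        # ordering: positively associated block gets the first letter
        assert pos_groups.iloc[0] == "A"

    def test_all_zero_matrix_flagged_degenerate(self):
        mat = pd.DataFrame(np.zeros((5, 3)),
                           index=[f"ct{i}" for i in range(5)],
                           columns=list("xyz"))
        with pytest.warns(UserWarning, match="degenerate"):
            groups = cluster_association_profiles(mat)
        assert (groups == "A").all()

    def test_grouping_invariant_to_row_order(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.normal(size=(9, 4)),
                           index=[f"ct{i}" for i in range(9)],
                           columns=list("abcd"))
        g1 = cluster_association_profiles(mat, n_groups=3)
        shuffled = mat.sample(frac=1.0, random_state=3)
        g2 = cluster_association_profiles(shuffled, n_groups=3)
        for ct in mat.index:
            partners1 = set(g1.index[g1 == g1[ct]])
            partners2 = set(g2.index[g2 == g2[ct]])
            assert partners1 == partners2


class TestGroupComparisons:
    def test_mannwhitney_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=4)
        y = rng.normal(size=4) + 1.0
        scores = pd.DataFrame({"T0": np.concatenate([x, y])},
                              index=[f"s{i}" for i in range(8)])
        group = pd.Series(["a"] * 4 + ["b"] * 4, index=scores.index)
        out = group_comparisons(scores, "unpaired", group=group)
        assert out.loc[0, "statistic"] == pytest.approx(
            mannwhitney_u_oracle(x, y))
        # permutation-exact p: proportion of group splits at least as extreme
        from itertools import combinations
        pooled = np.concatenate([x, y])
        obs = abs(mannwhitney_u_oracle(x, y) - 8.0)
        count = sum(
            abs(mannwhitney_u_oracle(pooled[list(idx)],
                                     np.delete(pooled, list(idx))) - 8.0)
            >= obs - 1e-12
            for idx in combinations(range(8), 4))
        assert out.loc[0, "p"] == pytest.approx(count / 70, abs=1e-10)

    def test_identical_paired_vectors_degenerate_p_one(self):
        scores = pd.DataFrame({"T0": [1.0, 2, 3, 1, 2, 3]},
                              index=[f"s{i}" for i in range(6)])
        pair = pd.Series(["p1", "p2", "p3"] * 2, index=scores.index)
        cond = pd.Series(["pre"] * 3 + ["post"] * 3, index=scores.index)
        out = group_comparisons(scores, "paired", pair_ids=pair,
                                condition=cond)
        assert out.loc[0, "p"] == 1.0
        assert "degenerate" in out.loc[0, "flag"]

    def test_constant_nonzero_paired_differences_flagged(self):
        scores = pd.DataFrame({"T0": [1.0, 2, 3, 2, 3, 4]},
                              index=[f"s{i}" for i in range(6)])
        pair = pd.Series(["p1", "p2", "p3"] * 2, index=scores.index)
        cond = pd.Series(["pre"] * 3 + ["post"] * 3, index=scores.index)
        out = group_comparisons(scores, "longitudinal", pair_ids=pair,
                                condition=cond)
        assert out.loc[0, "p"] < 1e-300
        assert "constant difference" in out.loc[0, "flag"]

    def test_unmatched_pair_ids_rejected(self):
        scores = pd.DataFrame({"T0": [1.0, 2, 3, 4]},
                              index=[f"s{i}" for i in range(4)])
        pair = pd.Series(["p1", "p2", "p1", "p3"], index=scores.index)
        cond = pd.Series(["pre", "pre", "post", "post"], index=scores.index)
        with pytest.raises(ValueError, match="unmatched"):
            group_comparisons(scores, "paired", pair_ids=pair,
                              condition=cond)

    def test_paired_t_matches_scipy_on_clean_data(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=12)
        b = a + rng.normal(0.5, 1.0, size=12)
        scores = pd.DataFrame({"T0": np.concatenate([a, b])},
                              index=[f"s{i}" for i in range(24)])
        pair = pd.Series([f"p{i}" for i in range(12)] * 2,
                         index=scores.index)
        cond = pd.Series(["pre"] * 12 + ["post"] * 12, index=scores.index)
        out = group_comparisons(scores, "longitudinal", pair_ids=pair,
                                condition=cond)
        expected = stats.ttest_rel(a, b)
        assert out.loc[0, "p"] == pytest.approx(expected.pvalue)


class TestEndToEndRecovery:
    def test_planted_trait_effect_lands_in_positive_group(self, signatures):
        """Full synthetic loop: 8 bulk cohorts -> marker scoring -> cohort
        Spearman -> pooling -> association grouping puts the cell type with
        the planted positive effect in the positively associated group."""
        sig, mk = signatures
        ref = w.MarkerReference(markers=mk)
        tables = []
        for c in range(8):
            expr, traits, truth = w.simulate_bulk_cohort(
                sig, 80, {"homa": ("T4", 1.0)}, noise_sd=0.2, seed=100 + c)
            scores = w.score_samples(expr, ref)
            tables.append(cohort_correlations(scores.scores, traits))
        meta = meta_analyze(tables)
        assoc = w.clinical_meta.association_matrix(meta)
        groups = cluster_association_profiles(assoc.dropna(), n_groups=2,
                                              order_by=["homa"])
        pooled = meta.set_index("celltype")["rho_fixed"]
        assert pooled["T4"] > 0.5
        assert groups["T4"] == "A"
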