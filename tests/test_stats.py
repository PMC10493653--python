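"""Comparison layer: closed-form ANOVA/chi-square against library
cross-checks, exact rank tests against enumeration oracles, RM-ANOVA
against an independent implementation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sst

import dcahrv as d


class TestAnova:
    def test_summary_and_raw_agree_exactly(self):
        rng = np.random.default_rng(0)
        samples = [rng.normal(10, 2, 17), rng.normal(11, 2, 23),
                   rng.normal(10.5, 3, 19)]
        raw = d.anova_raw(samples)
        summ = d.anova_from_summary([d.summarize(s, str(i))
                                     for i, s in enumerate(samples)])
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        samples = [rng.normal(0, 1, 12), rng.normal(0.5, 1.5, 15),
                   rng.normal(-0.2, 0.8, 9)]
        mine = d.anova_raw(samples)
        ref = sst.f_oneway(*samples)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_equal_means_give_zero_f(self):
        gs = [d.GroupSummary("a", 10, 5.0, 1.0),
              d.GroupSummary("b", 20, 5.0, 2.0)]
        assert d.anova_from_summary(gs).statistic == 0.0

    def test_two_group_f_equals_t_squared(self):
        gs = [d.GroupSummary("a", 12, 5.0, 1.1),
              d.GroupSummary("b", 15, 5.8, 1.4)]
        F = d.anova_from_summary(gs).statistic
        # pooled-variance t on the same summaries
        sp2 = (11 * 1.1 ** 2 + 14 * 1.4 ** 2) / 25
        t = (5.0 - 5.8) / math.sqrt(sp2 * (1 / 12 + 1 / 15))
        assert F == pytest.approx(t ** 2, rel=1e-12)

    def test_degenerate_variance_errors(self):
        gs = [d.GroupSummary("a", 5, 1.0, 0.0),
              d.GroupSummary("b", 5, 1.0, 0.0)]
        with pytest.raises(ValueError):
            d.anova_from_summary(gs)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            d.anova_from_summary([d.GroupSummary("a", 1, 0, 1),
                                  d.GroupSummary("b", 5, 0, 1)])


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        t = np.array([[10, 30], [20, 60], [5, 15]])
        assert d.pearson_chi_square(t).statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_without_correction(self):
        t = np.array([[13, 32], [16, 34], [15, 35]])
        mine = d.pearson_chi_square(t)
        chi2, p, df, _ = sst.chi2_contingency(t, correction=False)
        assert mine.statistic == pytest.approx(chi2, rel=1e-12)
        assert mine.p == pytest.approx(p, rel=1e-12)
        assert mine.df == (df,)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.integers(1, 30, size=(3, 4)).astype(float)
        base = d.pearson_chi_square(t).statistic
        perm = d.pearson_chi_square(t[::-1, ::-1]).statistic
        assert perm == pytest.approx(base, rel=1e-12)

    def test_zero_margin_recommends_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            d.pearson_chi_square(np.array([[0, 0], [3, 4]]))


def fisher_oracle(table):
    """Full hypergeometric enumeration with binomial coefficients only."""
    (a, b), (c, c2) = table
    r1, r2, k = a + b, c + c2, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, k - x)) / math.comb(n, k)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, k - r2), min(r1, k) + 1)
               if prob(x) <= p_obs * (1 + 1e-7))


class TestFisher:
    @pytest.mark.parametrize("table", [
        [[1, 9], [10, 1]], [[5, 0], [0, 5]], [[3, 7], [5, 5]]])
    def test_matches_enumeration_oracle(self, table):
        res = d.fisher_exact(np.array(table))
        assert res.p == pytest.approx(fisher_oracle(table), rel=1e-9)
        ref = sst.fisher_exact(np.array(table))
        assert res.p == pytest.approx(ref.pvalue, rel=1e-7)

    def test_table_proportional_to_margins(self):
        assert d.fisher_exact(np.array([[4, 6], [2, 3]])).p == pytest.approx(1.0)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            d.fisher_exact(np.array([[1, 2, 3], [4, 5, 6]]))


def mw_oracle(x, y):
    """Two-sided permutation p for the Mann-Whitney U, counting pairwise
    wins directly (no ranks)."""
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0

    def u_of(idx):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        xs, ys = pooled[sel], pooled[~sel]
        return np.sum(xs[:, None] > ys[None, :]) \
            + 0.5 * np.sum(xs[:, None] == ys[None, :])

    u_obs = u_of(range(n1))
    hits = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_multisets_give_central_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = d.mann_whitney(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 5), rng.normal(0.8, 1, 5)
        res = d.mann_whitney(x, y, method="exact")
        assert res.p == pytest.approx(mw_oracle(x, y), rel=1e-12)

    def test_exact_with_ties_matches_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 3.0, 4.0, 4.0])
        res = d.mann_whitney(x, y, method="exact")
        assert res.p == pytest.approx(mw_oracle(x, y), rel=1e-12)

    def test_extreme_separation_minimal_p(self):
        x = np.array([10.0, 11.0, 12.0, 13.0])
        y = np.array([0.0, 1.0, 2.0])
        res = d.mann_whitney(x, y, method="exact")
        # the observed labeling is the unique most extreme one in each tail
        assert res.p == pytest.approx(2 / math.comb(7, 4))

    def test_approx_matches_scipy(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 25), rng.normal(0.4, 1, 30)
        mine = d.mann_whitney(x, y, method="approx")
        ref = sst.mannwhitneyu(x, y, method="asymptotic",
                               use_continuity=False)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            d.mann_whitney([], [1.0])


def wsr_oracle(diffs):
    """Exact signed-rank p by sign enumeration with hand-rolled midranks."""
    dv = np.asarray(diffs, dtype=float)
    dv = dv[dv != 0]
    absd = np.abs(dv)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(len(dv))
    i = 0
    pos = 1
    srt = absd[order]
    while i < len(dv):
        j = i
        while j < len(dv) and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (pos + (pos + (j - i) - 1)) / 2.0
        pos += j - i
        i = j
    w_obs = ranks[dv > 0].sum()
    mu = len(dv) * (len(dv) + 1) / 4.0
    hits = 0
    for signs in itertools.product((0, 1), repeat=len(dv)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / 2 ** len(dv)


class TestWilcoxon:
    def test_uniform_shift_gives_extreme_w(self):
        before = np.arange(1.0, 9.0)
        after = before + 2.0
        res = d.wilcoxon_signed_rank(before, after, method="exact")
        assert res.statistic == pytest.approx(8 * 9 / 2)
        assert res.p == pytest.approx(2 / 2 ** 8)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        before = rng.normal(0, 1, 8)
        after = before + rng.normal(0.5, 1, 8)
        res = d.wilcoxon_signed_rank(before, after, method="exact")
        assert res.p == pytest.approx(wsr_oracle(after - before), rel=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(8)
        before = rng.normal(0, 1, 10)
        after = before + rng.normal(0.3, 1, 10)
        res = d.wilcoxon_signed_rank(before, after, method="exact")
        ref = sst.wilcoxon(after, before, mode="exact")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            d.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestRepeatedMeasures:
    def test_identical_timepoints(self):
        m = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        results = d.repeated_measures_compare(m)
        assert results[0].statistic == 0.0
        assert all(r.p == 1.0 for r in results)

    def test_constructed_effect_detected(self):
        rng = np.random.default_rng(9)
        base = rng.normal(100, 5, 12)
        m = np.column_stack([base + rng.normal(0, 1, 12),
                             base + 20 + rng.normal(0, 1, 12),
                             base + rng.normal(0, 1, 12)])
        results = d.repeated_measures_compare(m)
        assert results[0].p < 0.001          # overall within-subject effect
        assert results[1].p < 0.05           # baseline vs shifted timepoint
        assert results[3].p < 0.05           # shifted vs recovered timepoint
        assert results[2].p > 0.05           # baseline vs recovered

    def test_matches_pingouin_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(10)
        m = rng.normal(0, 1, (9, 3)) + rng.normal(0, 1, (9, 1))
        mine = d.repeated_measures_compare(m)[0]
        long = pd.DataFrame({
            "y": m.ravel(),
            "subject": np.repeat(np.arange(9), 3),
            "time": np.tile(np.arange(3), 9)})
        ref = pg.rm_anova(data=long, dv="y", within="time", subject="subject")
        assert mine.statistic == pytest.approx(float(ref["F"][0]), rel=1e-6)
        assert mine.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_bonferroni_rule(self):
        assert d.bonferroni(0.02, 3) == pytest.approx(0.06)
        assert d.bonferroni(0.5, 3) == 1.0

    def test_missing_cells_rejected(self):
        m = np.ones((5, 3))
        m[2, 1] = np.nan
        with pytest.raises(ValueError):
            d.repeated_measures_compare(m)


class TestKSNormality:
    def test_hand_computed_d(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        res = d.ks_normality(x)
        m, s = x.mean(), x.std(ddof=1)
        cdf = sst.norm.cdf(np.sort(x), m, s)
        n = len(x)
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert res.statistic == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_normal_sample_not_rejected(self):
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(5, 2, 200)
            hits += d.ks_normality(x).p > 0.05
        assert hits >= 9

    def test_heavy_tailed_sample_rejected(self):
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).standard_cauchy(500)
            hits += d.ks_normality(x).p < 0.05
        assert hits >= 9

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            d.ks_normality(np.full(10, 3.0))
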