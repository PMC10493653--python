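"""Group-comparison statistics, including closed-form reconstruction from
published summaries.

The centrepiece is one-way ANOVA computed directly from per-group
(n, mean, SD) triplets — the form in which clinical tables publish their
data — so printed F statistics can be recomputed without raw values:

    F = [ sum n_i (m_i - m̄)^2 / (k-1) ] / [ sum (n_i - 1) s_i^2 / (N-k) ]

with m̄ the n-weighted grand mean. Pearson chi-square plays the same role
for count tables. The nonparametric tests (Mann-Whitney, Wilcoxon
signed-rank) switch between exact enumeration for small samples and
tie-corrected normal approximations; the repeated-measures layer is a
one-way within-subject ANOVA with Bonferroni-adjusted pairwise follow-ups.

All SDs are taken as sample (n-1) SDs, matching standard statistical
package output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sst


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: n, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class CountTable:
    """Labelled r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("count table must be at least 2x2")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def summarize(values, label: str = "") -> GroupSummary:
    x = np.asarray(values, dtype=float)
    return GroupSummary(label=label, n=x.size, mean=float(np.mean(x)),
                        sd=float(np.std(x, ddof=1)))


def anova_from_summary(groups: Sequence[GroupSummary]) -> TestResult:
    """One-way ANOVA F from per-group (n, mean, SD) summaries."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        g.validate()
    ns = np.array([g.n for g in groups], dtype=float)
    ms = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    N, k = ns.sum(), len(groups)
    grand = float(np.sum(ns * ms) / N)
    ss_between = float(np.sum(ns * (ms - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds ** 2))
    df1, df2 = k - 1, int(N) - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("F undefined: zero between- and within-group variance")
        return TestResult(float("inf"), (df1, df2), 0.0, "one-way ANOVA (summary)")
    F = (ss_between / df1) / (ss_within / df2)
    return TestResult(float(F), (df1, df2), float(sst.f.sf(F, df1, df2)),
                      "one-way ANOVA (summary)")


def anova_raw(samples: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA on raw samples; exactly the summary form applied to
    each sample's own (n, mean, sd)."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    gs = []
    for i, s in enumerate(samples):
        x = np.asarray(s, dtype=float)
        if x.size < 2:
            raise ValueError(f"group {i}: n must be >= 2")
        gs.append(summarize(x, label=str(i)))
    res = anova_from_summary(gs)
    return TestResult(res.statistic, res.df, res.p, "one-way ANOVA")


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    t = table.counts if isinstance(table, CountTable) else \
        CountTable(np.asarray(table)).counts
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin: use fisher_exact instead")
    E = np.outer(row, col) / t.sum()
    chi2 = float(np.sum((t - E) ** 2 / E))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(chi2, (df,), float(sst.chi2.sf(chi2, df)),
                      "Pearson chi-square")


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.
    """
    t = table.counts if isinstance(table, CountTable) else \
        CountTable(np.asarray(table)).counts
    if t.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    dist = sst.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p = float(np.sum(pmf[pmf <= dist.pmf(a) * (1 + 1e-7)]))
    return TestResult(float(a), (1,), min(p, 1.0), "Fisher exact")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sst.rankdata(np.concatenate([x, y]))
    r1 = float(np.sum(ranks[: x.size]))
    return r1 - x.size * (x.size + 1) / 2.0


def mann_whitney(x, y, method: str = "auto") -> TestResult:
    """Mann-Whitney U test for two independent samples.

    ``method``: "exact" enumerates all C(n1+n2, n1) group labelings of the
    pooled sample (mid-ranks, so ties are handled); "approx" uses the
    tie-corrected normal approximation; "auto" picks exact when both sides
    have at most 8 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if method == "auto":
        method = "exact" if max(n1, n2) <= 8 else "approx"
    if method == "exact":
        ranks = sst.rankdata(np.concatenate([x, y]))
        offset = n1 * (n1 + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return TestResult(u_obs, (n1, n2), hits / total, "Mann-Whitney U (exact)")
    # tie-corrected normal approximation
    pooled = np.concatenate([x, y])
    _, t_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(t_counts ** 3 - t_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return TestResult(u_obs, (n1, n2), 1.0, "Mann-Whitney U (approx)")
    z = (u_obs - mu) / math.sqrt(sigma2)
    p = float(2 * sst.norm.sf(abs(z)))
    return TestResult(u_obs, (n1, n2), min(p, 1.0), "Mann-Whitney U (approx)")


def wilcoxon_signed_rank(before, after, method: str = "auto") -> TestResult:
    """Wilcoxon signed-rank test for paired samples (differences after-before).

    Zero differences are dropped. ``method``: "exact" enumerates all 2^n
    sign patterns of the observed |difference| ranks; "approx" is the
    tie-corrected normal approximation; "auto" picks exact for n <= 15.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences zero: test degenerate")
    ranks = sst.rankdata(np.abs(d))
    w_pos = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    if method == "auto":
        method = "exact" if n <= 15 else "approx"
    if method == "exact":
        dev_obs = abs(w_pos - mu)
        hits = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(np.sum(ranks[np.asarray(signs, dtype=bool)]))
            if abs(w - mu) >= dev_obs - 1e-9:
                hits += 1
        return TestResult(w_pos, (n,), hits / 2 ** n, "Wilcoxon signed-rank (exact)")
    _, t_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 \
        - np.sum(t_counts ** 3 - t_counts) / 48.0
    if sigma2 <= 0:
        return TestResult(w_pos, (n,), 1.0, "Wilcoxon signed-rank (approx)")
    z = (w_pos - mu) / math.sqrt(sigma2)
    p = float(2 * sst.norm.sf(abs(z)))
    return TestResult(w_pos, (n,), min(p, 1.0), "Wilcoxon signed-rank (approx)")


def repeated_measures_compare(matrix) -> list[TestResult]:
    """One-way repeated-measures ANOVA over three timepoints plus
    Bonferroni-adjusted pairwise paired t-tests.

    ``matrix`` is subjects x 3 (e.g. before / after / 1-month follow-up)
    with no missing cells. Returns [overall F, pair(0,1), pair(0,2),
    pair(1,2)]; pairwise p-values are multiplied by 3 and capped at 1.
    No sphericity correction is applied.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("matrix must be subjects x 3 timepoints")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not supported")
    n, t = m.shape
    grand = m.mean()
    ss_subj = t * float(np.sum((m.mean(axis=1) - grand) ** 2))
    ss_time = n * float(np.sum((m.mean(axis=0) - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_err = max(ss_total - ss_subj - ss_time, 0.0)
    df1, df2 = t - 1, (n - 1) * (t - 1)
    if ss_time <= 1e-12 * max(ss_total, 1.0):
        overall = TestResult(0.0, (df1, df2), 1.0, "RM-ANOVA")
    elif ss_err == 0.0:
        overall = TestResult(float("inf"), (df1, df2), 0.0, "RM-ANOVA")
    else:
        F = (ss_time / df1) / (ss_err / df2)
        overall = TestResult(float(F), (df1, df2), float(sst.f.sf(F, df1, df2)),
                             "RM-ANOVA")
    results = [overall]
    for i, j in ((0, 1), (0, 2), (1, 2)):
        d = m[:, j] - m[:, i]
        if np.allclose(d, 0):
            results.append(TestResult(0.0, (n - 1,), 1.0,
                                      f"paired t {i}v{j} (Bonferroni)"))
            continue
        stat, p = sst.ttest_rel(m[:, j], m[:, i])
        results.append(TestResult(float(stat), (n - 1,),
                                  min(float(p) * 3.0, 1.0),
                                  f"paired t {i}v{j} (Bonferroni)"))
    return results


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: p * m, capped at 1."""
    return min(p * m, 1.0)


def ks_normality(values) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with the sample's own mean and SD (asymptotic p, no small-sample
    correction — the legacy statistical-package convention)."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    m, s = float(np.mean(x)), float(np.std(x, ddof=1))
    if s == 0:
        raise ValueError("zero variance: KS test degenerate")
    res = sst.kstest(x, "norm", args=(m, s), mode="asymp")
    return TestResult(float(res.statistic), (x.size,), float(res.pvalue),
                      "one-sample KS (normal)")
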