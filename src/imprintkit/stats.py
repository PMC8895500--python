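"""Group-comparison statistics used across the imprinting analyses.

The study design compares embryo groups two ways: across the three Zfp57
genotypes within one sex (omnibus Kruskal-Wallis for allelic expression;
one-way ANOVA with Fisher's LSD for expression levels and ICR methylation),
and across sexes within one genotype (two-tailed Student's t-test).  These
wrappers pin down the exact conventions — tie handling, degenerate inputs,
significance stars — so every module reports comparisons identically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "kruskal_wallis",
    "binomial_allelic_test",
    "anova_fisher_lsd",
    "two_tailed_ttest",
    "welch_ttest",
    "star_label",
    "AnovaLsdResult",
]


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(out):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    return out


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across two or more groups.

    Mid-ranks with the standard tie correction.  All-identical input (zero
    rank variance) returns ``(0.0, 1.0)`` rather than failing: a constant
    dataset carries no evidence of a group difference.

    Returns ``(H, p)`` with the p-value from the chi-square approximation
    at ``k - 1`` degrees of freedom.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*gs)
    return float(h), float(p)


def binomial_allelic_test(maternal_count: int, paternal_count: int) -> float:
    """Exact two-sided binomial test of allelic balance (null proportion 0.5).

    Tests whether the paternal read count departs from the 50:50 split
    expected for a biallelically expressed gene.
    """
    n = maternal_count + paternal_count
    if n <= 0:
        raise ValueError("binomial test needs at least one allelic read")
    return float(sps.binomtest(paternal_count, n, 0.5, alternative="two-sided").pvalue)


@dataclass
class AnovaLsdResult:
    """One-way ANOVA with Fisher's least-significant-difference follow-up."""

    f_statistic: float
    p_value: float
    #: pairwise (i, j) -> two-sided p from a t on the pooled MSE, df = N - k
    pairwise_p: dict[tuple[int, int], float]
    #: True when the omnibus p < alpha, i.e. the LSD comparisons are protected
    protected: bool
    mse: float
    df_within: int


def anova_fisher_lsd(groups, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA with Fisher LSD pairwise comparisons.

    Fisher's LSD tests each pair with a t statistic built on the pooled
    within-group mean square (MSE) at ``N - k`` degrees of freedom.  All
    pairwise p-values are reported; ``protected`` records whether the
    omnibus F cleared ``alpha`` (the classical gate for reading them).
    """
    gs = _as_groups(groups)
    if len(gs) < 3:
        raise ValueError(
            "anova_fisher_lsd needs at least three groups; "
            "use two_tailed_ttest for a two-group comparison"
        )
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than two values")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    df_within = n_total - k
    means = [float(g.mean()) for g in gs]
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    mse = sse / df_within

    if mse == 0.0:
        # all groups internally constant: F degenerates; fall back on means
        all_equal = len(set(means)) == 1
        f_stat = 0.0 if all_equal else float("inf")
        p_omni = 1.0 if all_equal else 0.0
    else:
        f_stat, p_omni = (float(x) for x in sps.f_oneway(*gs))

    pairwise: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(mse * (1.0 / gs[i].size + 1.0 / gs[j].size))
            if se == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                t = diff / se
                p = 2.0 * float(sps.t.sf(abs(t), df_within))
            pairwise[(i, j)] = p

    return AnovaLsdResult(
        f_statistic=f_stat,
        p_value=p_omni,
        pairwise_p=pairwise,
        protected=p_omni < alpha,
        mse=mse,
        df_within=df_within,
    )


def two_tailed_ttest(group_a, group_b) -> float:
    """Two-tailed Student's t-test (pooled variance) p-value.

    Degenerate inputs follow a documented convention: when the pooled
    variance is zero, identical group means give p = 1.0 (no evidence of a
    difference) and distinct means give p = 0.0 (the separation is exact).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs at least two values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def welch_ttest(group_a, group_b) -> float:
    """Two-tailed Welch (unequal-variance) t-test p-value.

    Same degenerate-variance convention as :func:`two_tailed_ttest`.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs at least two values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def star_label(p_value: float) -> str:
    """Figure-style significance stars: * <0.05, ** <0.01, *** <0.001, ns."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value out of range: {p_value}")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"
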