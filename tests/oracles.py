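"""Independent brute-force oracles for the statistical machinery.

These are deliberately naive textbook implementations (explicit ranking,
explicit sums of squares, full tail enumeration) kept separate from the
package so the two routes share no code.
"""
from __future__ import annotations

import math

import numpy as np


def brute_kruskal_wallis(groups: list[list[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H by explicit mid-ranking with tie correction."""
    from scipy.stats import chi2  # p-value transform only

    pooled = [x for g in groups for x in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    h = 0.0
    idx = 0
    for g in groups:
        r_sum = sum(ranks[idx: idx + len(g)])
        idx += len(g)
        h += r_sum * r_sum / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    ties = {}
    for x in pooled:
        ties[x] = ties.get(x, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    if correction == 0.0:
        return 0.0, 1.0
    h /= correction
    df = len(groups) - 1
    return h, float(chi2.sf(h, df))


def brute_binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial p by enumerating all outcomes at least as
    improbable as the observed one (the minlike convention)."""
    probs = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    observed = probs[k]
    # tolerate float fuzz when comparing point probabilities
    total = sum(q for q in probs if q <= observed * (1 + 1e-12))
    return min(1.0, total)


def brute_anova_lsd(groups: list[list[float]]) -> tuple[float, float, dict]:
    """One-way ANOVA by explicit sums of squares + Fisher LSD pairwise t."""
    from scipy.stats import f as fdist, t as tdist

    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups)
    df_b, df_w = k - 1, n - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f_stat = ms_b / ms_w
    p = float(fdist.sf(f_stat, df_b, df_w))
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(ms_w * (1 / len(groups[i]) + 1 / len(groups[j])))
            t = (np.mean(groups[i]) - np.mean(groups[j])) / se
            pairwise[(i, j)] = 2.0 * float(tdist.sf(abs(t), df_w))
    return f_stat, p, pairwise


def brute_pooled_ttest(a: list[float], b: list[float]) -> tuple[float, float]:
    """Student's pooled-variance t statistic and two-sided p, by formula."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma, mb = np.mean(a), np.mean(b)
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2.0 * float(tdist.sf(abs(t), na + nb - 2))


def naive_site_levels(calls) -> dict:
    """Recount per-(sample, chrom, pos) methylation from raw call rows."""
    acc: dict[tuple, list[int]] = {}
    for row in calls.itertuples(index=False):
        acc.setdefault((row.sample, row.chrom, row.pos), []).append(
            1 if row.state == "methylated" else 0
        )
    return {key: (sum(v), len(v)) for key, v in acc.items()}


def naive_clone_set_percent(patterns: list[tuple[int, ...]]) -> float:
    """Clone-set methylation by a double loop over CpG states."""
    meth = total = 0
    for pattern in patterns:
        for state in pattern:
            total += 1
            if state:
                meth += 1
    return 100.0 * meth / total
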