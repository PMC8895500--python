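"""P-score allelic-expression analysis of imprinted genes.

The P-score centres the paternal-allele read proportion at zero:

    P-score = P / (M + P) - 0.5

where P and M are paternal- and maternal-allele read counts for one gene in
one embryo.  0.5 means exclusively paternal expression, -0.5 exclusively
maternal, 0 biallelic.  A gene "switches" when loss of the imprinting
maintenance factor moves its group-mean P-score toward zero; switches are
selected by an omnibus Kruskal-Wallis test across the three genotypes
within one sex combined with a group-mean difference threshold
(delta-P >= 0.1, p < 0.05).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GENOTYPES, AllelicCountRecord
from .stats import binomial_allelic_test as _binom_test
from .stats import kruskal_wallis

__all__ = [
    "filter_expressed_allelic",
    "compute_pscore",
    "pscore_table",
    "delta_pscore",
    "binomial_allelic_test",
    "select_switched_genes",
    "classify_allelic_state",
    "SwitchResult",
    "ALLELIC_STATES",
    "DEFAULT_STATE_CUTOFFS",
]

ALLELIC_STATES = (
    "maternal", "preferential_maternal", "slightly_maternal", "biallelic",
    "slightly_paternal", "preferential_paternal", "paternal",
)

#: |mean P-score| cutoffs separating biallelic / slightly / preferential /
#: monoallelic states.  Config-overridable; these defaults are printed into
#: every report.
DEFAULT_STATE_CUTOFFS = (0.1, 0.25, 0.4)


def filter_expressed_allelic(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose pooled maternal+paternal read count is not above
    ``min_total``.

    The filter pools M+P over all samples in the analysis set and keeps or
    drops each gene as a whole (all-or-none), using a strict inequality:
    a gene totalling exactly ``min_total`` reads is dropped.
    """
    if counts.empty:
        warnings.warn("filter_expressed_allelic: empty count table", stacklevel=2)
        return counts.copy()
    pooled = counts.groupby("gene")[["maternal_count", "paternal_count"]].sum().sum(axis=1)
    keep = pooled[pooled > min_total].index
    return counts[counts["gene"].isin(keep)].reset_index(drop=True)


def compute_pscore(record: AllelicCountRecord) -> float:
    """P-score of one allelic count record: P/(M+P) - 0.5.

    Raises if the record has no allelic reads (such records must be
    removed by :func:`filter_expressed_allelic` first).
    """
    total = record.maternal_count + record.paternal_count
    if total == 0:
        raise ValueError(
            f"P-score undefined for {record.gene_id}/{record.sample_id}: "
            "no allelic reads (filter the table first)"
        )
    return record.paternal_count / total - 0.5


def pscore_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorised P-scores for a filtered count table.

    Rows with zero allelic reads get NaN (they carry no allelic
    information for this gene; the pooled gene filter has already run).

    Returns columns ``gene``, ``sample``, ``pscore``.
    """
    total = counts["maternal_count"] + counts["paternal_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(total > 0, counts["paternal_count"] / total - 0.5, np.nan)
    return pd.DataFrame({
        "gene": counts["gene"].to_numpy(),
        "sample": counts["sample"].to_numpy(),
        "pscore": score,
    })


def delta_pscore(scores_a, scores_b) -> float:
    """Absolute difference of group-mean P-scores between two groups."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("delta_pscore: both groups must be non-empty")
    return abs(float(a.mean()) - float(b.mean()))


def binomial_allelic_test(record: AllelicCountRecord) -> float:
    """Exact two-sided binomial test of a record's allelic balance."""
    return _binom_test(record.maternal_count, record.paternal_count)


@dataclass
class SwitchResult:
    """Switch-selection outcome for one gene in one genotype contrast."""

    gene_id: str
    delta_pscore: float
    h_statistic: float
    p_value: float
    comparison: str
    selected: bool
    mean_a: float
    mean_b: float


def select_switched_genes(
    pscores: pd.DataFrame,
    samples: pd.DataFrame,
    sex: str,
    pair: tuple[str, str],
    delta_threshold: float = 0.1,
    alpha: float = 0.05,
) -> tuple[list[SwitchResult], pd.DataFrame, pd.DataFrame]:
    """Select genes whose allelic expression switches between two genotypes.

    Within the given sex, each gene is tested with an omnibus
    Kruskal-Wallis across all three genotypes; delta-P is the absolute
    difference of group-mean P-scores for the named genotype ``pair``.  A
    gene is selected iff delta-P >= ``delta_threshold`` and the omnibus
    p < ``alpha``.

    Returns ``(results, heatmap, intensity_diff)``: per-gene results, a
    genes x samples matrix of per-sample P-scores (columns ordered M+Z+,
    M-Z+, M-Z-, selected genes only), and the same matrix expressed as
    deviation from the first pair genotype's mean (the "intensity
    difference" view).
    """
    sub = samples[samples["sex"] == sex]
    for genotype in GENOTYPES:
        if not (sub["genotype"] == genotype).any():
            raise ValueError(
                f"no {sex} samples with genotype {genotype}: the omnibus test "
                "needs all three genotypes"
            )
    for genotype in pair:
        if genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype in pair: {genotype!r}")
    sample_order = [
        s for genotype in GENOTYPES
        for s in sub.loc[sub["genotype"] == genotype, "sample"]
    ]
    geno_of = dict(zip(sub["sample"], sub["genotype"]))
    scores = pscores[pscores["sample"].isin(geno_of)].dropna(subset=["pscore"])

    results: list[SwitchResult] = []
    comparison = f"{sex}:{pair[0]} vs {pair[1]}"
    for gene, gdf in scores.groupby("gene", sort=True):
        by_geno = {
            genotype: gdf.loc[gdf["sample"].map(geno_of) == genotype, "pscore"].to_numpy()
            for genotype in GENOTYPES
        }
        missing = [g for g, v in by_geno.items() if v.size == 0]
        if missing:
            raise ValueError(f"gene {gene}: no P-scores in genotype group(s) {missing}")
        _h, p = kruskal_wallis(*by_geno.values())
        dp = delta_pscore(by_geno[pair[0]], by_geno[pair[1]])
        results.append(SwitchResult(
            gene_id=str(gene),
            delta_pscore=dp,
            h_statistic=_h,
            p_value=p,
            comparison=comparison,
            selected=bool(dp >= delta_threshold and p < alpha),
            mean_a=float(by_geno[pair[0]].mean()),
            mean_b=float(by_geno[pair[1]].mean()),
        ))

    selected_genes = [r.gene_id for r in results if r.selected]
    heat = (
        scores[scores["gene"].isin(selected_genes)]
        .pivot_table(index="gene", columns="sample", values="pscore")
        .reindex(index=selected_genes, columns=sample_order)
    )
    heat.index.name = "gene"
    ref_samples = [s for s in sample_order if geno_of[s] == pair[0]]
    intensity = heat.sub(heat[ref_samples].mean(axis=1), axis=0)
    return results, heat, intensity


def classify_allelic_state(group_scores,
                           cutoffs: tuple[float, float, float] = DEFAULT_STATE_CUTOFFS,
                           ) -> str:
    """Classify a gene's allelic state in one group from its mean P-score.

    With default cutoffs (0.1, 0.25, 0.4): |mean| < 0.1 is biallelic,
    then slightly / preferential / fully monoallelic bands; the sign picks
    maternal (negative) versus paternal (positive).
    """
    scores = np.asarray(group_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("classify_allelic_state: empty group")
    lo, mid, hi = cutoffs
    if not 0 < lo < mid < hi:
        raise ValueError(f"cutoffs must be increasing and positive: {cutoffs}")
    mean = float(scores.mean())
    mag = abs(mean)
    if mag < lo:
        return "biallelic"
    side = "paternal" if mean > 0 else "maternal"
    if mag < mid:
        return f"slightly_{side}"
    if mag < hi:
        return f"preferential_{side}"
    return side


def switch_results_frame(results: list[SwitchResult],
                         state_by_group: dict[str, dict[str, str]] | None = None,
                         ) -> pd.DataFrame:
    """Tabulate switch results (+ optional per-group state labels) for export."""
    df = pd.DataFrame([{
        "gene": r.gene_id,
        "comparison": r.comparison,
        "delta_pscore": r.delta_pscore,
        "H": r.h_statistic,
        "p_value": r.p_value,
        "selected": r.selected,
        "mean_pscore_a": r.mean_a,
        "mean_pscore_b": r.mean_b,
    } for r in results])
    if state_by_group:
        for group, mapping in state_by_group.items():
            df[f"state_{group}"] = df["gene"].map(mapping)
    return df
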