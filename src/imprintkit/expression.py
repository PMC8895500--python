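"""Expression-level analysis of imprinted genes (TPM, fold change, tests).

Expression is quantified as transcripts per million (TPM): per sample,
each gene's read count is divided by its transcript length, and the
length-normalised rates are scaled to sum to 10^6.  Group contrasts use
log2 fold changes of mean TPM with strict thresholds (|log2FC| > 0.5 for
genotype contrasts, > 0.3 for the sex contrast), a per-gene two-group
test, and one-way ANOVA with Fisher's LSD for three-genotype comparisons.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import anova_fisher_lsd, two_tailed_ttest, welch_ttest

__all__ = [
    "compute_tpm",
    "filter_quantifiable",
    "log2_fold_change",
    "differential_genes",
    "DifferentialResult",
    "anova_fisher_lsd",
    "two_tailed_ttest",
]


def compute_tpm(counts: pd.DataFrame, lengths: pd.DataFrame) -> pd.DataFrame:
    """Compute TPM from a long count table and a gene-length table.

    ``counts`` needs columns ``gene``, ``sample``, ``count``; ``lengths``
    needs ``gene``, ``length_bp``.  Per sample,
    TPM_g = (count_g / length_g) / sum_h(count_h / length_h) * 1e6.
    A sample with zero total counts gets all-zero TPM with a warning.

    Returns ``gene, sample, count, length_bp, tpm``.
    """
    length_of = dict(zip(lengths["gene"], lengths["length_bp"]))
    missing = sorted(set(counts["gene"]) - set(length_of))
    if missing:
        raise ValueError(f"no gene length for: {', '.join(map(str, missing))}")
    df = counts.copy()
    df["length_bp"] = df["gene"].map(length_of)
    if (df["length_bp"] <= 0).any():
        bad = df.loc[df["length_bp"] <= 0, "gene"].unique()
        raise ValueError(f"non-positive gene length for: {', '.join(map(str, bad))}")
    rate = df["count"] / df["length_bp"]
    denom = rate.groupby(df["sample"]).transform("sum")
    zero_samples = denom[denom == 0].index
    if len(zero_samples) > 0:
        warnings.warn(
            "compute_tpm: sample(s) with zero total counts get all-zero TPM",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        df["tpm"] = np.where(denom > 0, rate / denom * 1e6, 0.0)
    return df[["gene", "sample", "count", "length_bp", "tpm"]]


def filter_quantifiable(expression: pd.DataFrame, min_reads: int = 10,
                        min_tpm: float = 1.0) -> pd.DataFrame:
    """Keep genes with pooled raw count above ``min_reads`` and TPM above
    ``min_tpm`` in at least one sample (both strict inequalities)."""
    if expression.empty:
        return expression.copy()
    pooled = expression.groupby("gene")["count"].sum()
    max_tpm = expression.groupby("gene")["tpm"].max()
    keep = pooled.index[(pooled > min_reads) & (max_tpm > min_tpm)]
    return expression[expression["gene"].isin(keep)].reset_index(drop=True)


def log2_fold_change(group_a, group_b, pseudocount: float = 0.0) -> float:
    """log2 of the ratio of group-mean values (TPM), with optional pseudocount.

    log2FC = log2((mean_a + pseudocount) / (mean_b + pseudocount)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("log2_fold_change: both groups must be non-empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    denom = b.mean() + pseudocount
    if denom == 0:
        raise ValueError("log2_fold_change: denominator group mean is zero "
                         "(use a pseudocount)")
    return float(np.log2((a.mean() + pseudocount) / denom))


@dataclass
class DifferentialResult:
    """Differential-expression outcome for one gene in one contrast."""

    gene_id: str
    log2fc: float
    p_value: float
    comparison: str
    significant: bool
    mean_tpm_a: float
    mean_tpm_b: float


def differential_genes(
    expression: pd.DataFrame,
    samples: pd.DataFrame,
    group_a: pd.Index | list[str],
    group_b: pd.Index | list[str],
    comparison: str = "",
    fc_threshold: float = 0.5,
    alpha: float = 0.05,
    pseudocount: float = 0.0,
) -> tuple[list[DifferentialResult], pd.DataFrame]:
    """Per-gene differential expression between two sample groups.

    The fold change is the ratio of group-mean TPM (pseudocount 0 by
    default; a gene silent in one group gets an infinite log2FC rather
    than an error).  The p-value comes from a Welch t-test on
    log2(TPM + 1) — an ordinary two-group location test on the stabilised
    scale.  A gene is significant iff |log2FC| is strictly above
    ``fc_threshold`` and p < ``alpha``.

    Returns the per-gene results and a genes x samples TPM matrix
    restricted to significant genes (columns: group A then group B).
    """
    ga, gb = list(group_a), list(group_b)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("differential_genes: both groups need >= 2 samples")
    tpm = expression.pivot_table(index="gene", columns="sample", values="tpm")
    missing = [s for s in ga + gb if s not in tpm.columns]
    if missing:
        raise ValueError(f"samples absent from expression table: {missing}")
    results: list[DifferentialResult] = []
    for gene, row in tpm.iterrows():
        a = row[ga].to_numpy(dtype=float)
        b = row[gb].to_numpy(dtype=float)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if mean_b + pseudocount == 0 and mean_a + pseudocount == 0:
            lfc = 0.0
        elif mean_b + pseudocount == 0:
            lfc = float("inf")
        elif mean_a + pseudocount == 0:
            lfc = float("-inf")
        else:
            lfc = log2_fold_change(a, b, pseudocount)
        p = welch_ttest(np.log2(a + 1.0), np.log2(b + 1.0))
        results.append(DifferentialResult(
            gene_id=str(gene),
            log2fc=lfc,
            p_value=p,
            comparison=comparison,
            significant=bool(abs(lfc) > fc_threshold and p < alpha),
            mean_tpm_a=mean_a,
            mean_tpm_b=mean_b,
        ))
    sig = [r.gene_id for r in results if r.significant]
    matrix = tpm.reindex(index=sig, columns=ga + gb)
    matrix.index.name = "gene"
    return results, matrix


def differential_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Tabulate differential results for TSV export."""
    return pd.DataFrame([{
        "gene": r.gene_id,
        "comparison": r.comparison,
        "log2fc": r.log2fc,
        "p_value": r.p_value,
        "significant": r.significant,
        "mean_tpm_a": r.mean_tpm_a,
        "mean_tpm_b": r.mean_tpm_b,
    } for r in results])
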