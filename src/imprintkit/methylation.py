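"""ICR DNA-methylation quantification from read-level bisulfite CpG calls.

Per CpG site and embryo, the methylation level is the fraction of unique
covering reads that report a methylated cytosine; a site qualifies for the
total (non-allelic) quantification only when it is seen in at least three
unique reads.  An ICR's methylation percentage is the unweighted mean of
its qualifying per-site levels, times 100.  The allele-split variant
restricts calls to reads tagged maternal or paternal (via strain SNPs) and
relaxes the coverage rule to one unique read per site.  A region with no
qualifying site reports "no data", never a silent zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ALLELE_TAGS, CONFLICTING, MATERNAL, PATERNAL, UNASSIGNED, \
    ICRRegion, SnpTable
from .io import format_bedgraph
from .stats import anova_fisher_lsd, star_label, two_tailed_ttest

__all__ = [
    "assign_allele",
    "deduplicate_reads",
    "site_methylation",
    "site_methylation_table",
    "icr_methylation",
    "allelic_icr_methylation",
    "icr_methylation_by_sample",
    "compare_icr_groups",
    "export_methylation_track",
    "ICRMethylation",
    "NO_DATA",
]

#: Sentinel for "no qualifying reads at this region" — distinct from 0%.
NO_DATA = float("nan")


def _bisulfite_compatible(observed: str, allele_base: str, orientation: str) -> bool:
    """Does an observed base match an allele base under bisulfite chemistry?

    On the original-top orientation an unmethylated C reads as T, so an
    observed T is compatible with a C allele base; on the reverse
    orientation the complementary G reads as A.  Only the conversion of
    the read's own orientation applies — treating both as compatible at
    once would blind every A/G and C/T SNP.
    """
    if observed == allele_base:
        return True
    if orientation == "forward" and allele_base == "C" and observed == "T":
        return True
    if orientation == "reverse" and allele_base == "G" and observed == "A":
        return True
    return False


def assign_allele(read_observations: list[tuple[str, int, str]],
                  snps: SnpTable, orientation: str = "forward") -> tuple[str, int]:
    """Assign a read to a parental allele from its bases at strain SNPs.

    ``read_observations`` is a list of (chrom, pos, observed_base);
    ``orientation`` is the read's bisulfite orientation ('forward' =
    original top strand, C-to-T converted; 'reverse' = G-to-A).  Every
    informative position agreeing with the maternal (129) base gives
    'maternal'; all agreeing with the paternal (DBA) base gives
    'paternal'; a mixture is 'conflicting'; no informative position is
    'unassigned'.  A position whose observed base is bisulfite-compatible
    with both alleles (e.g. T at a C/T SNP on a forward read) casts no
    vote.  Observations at non-SNP positions are ignored; their count is
    returned alongside the tag.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be 'forward' or 'reverse', "
                         f"got {orientation!r}")
    maternal_votes = paternal_votes = 0
    ignored = 0
    for chrom, pos, base in read_observations:
        key = (chrom, int(pos))
        if key not in snps.entries:
            ignored += 1
            continue
        m_base, p_base = snps.entries[key]
        base = base.upper()
        m_ok = _bisulfite_compatible(base, m_base, orientation)
        p_ok = _bisulfite_compatible(base, p_base, orientation)
        if m_ok and not p_ok:
            maternal_votes += 1
        elif p_ok and not m_ok:
            paternal_votes += 1
        # compatible with both (bisulfite-degenerate) or neither: uninformative
    if maternal_votes and paternal_votes:
        return CONFLICTING, ignored
    if maternal_votes:
        return MATERNAL, ignored
    if paternal_votes:
        return PATERNAL, ignored
    return UNASSIGNED, ignored


DEDUP_KEY = ["sample", "read_start", "read_end", "strand"]


def deduplicate_reads(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse PCR-duplicate reads in a methylation call table.

    Reads are duplicates when they share (sample, alignment start, end,
    strand); one representative read (the first by read_id) survives per
    group, keeping all of its CpG calls.  Returns the deduplicated table
    and the per-group duplicate multiplicities.
    """
    missing = [c for c in DEDUP_KEY if c not in calls.columns]
    if missing:
        raise ValueError(
            f"deduplicate_reads: calls table lacks coordinate column(s) {missing}"
        )
    if calls.empty:
        return calls.copy(), pd.Series(dtype=int)
    reads = calls.drop_duplicates(["sample", "read_id"])
    keeper = (reads.sort_values("read_id")
                   .groupby(DEDUP_KEY, sort=False)["read_id"].first())
    sizes = reads.groupby(DEDUP_KEY, sort=False)["read_id"].nunique()
    kept = calls.merge(
        keeper.rename("keep_id").reset_index(),
        on=DEDUP_KEY, how="left",
    )
    out = kept[kept["read_id"] == kept["keep_id"]].drop(columns="keep_id")
    return out.reset_index(drop=True), sizes


def site_methylation(states, min_reads: int = 3) -> float:
    """Methylation level of one CpG site in one sample, or NaN if excluded.

    ``states`` are the deduplicated per-read calls at the site ('methylated'
    or 'unmethylated' / booleans).  The level is methylated/total when the
    site is covered by at least ``min_reads`` unique reads; otherwise the
    site is excluded (NaN — deliberately distinct from a level of 0).
    """
    arr = [s if isinstance(s, (bool, np.bool_)) else s == "methylated" for s in states]
    if len(arr) < min_reads:
        return NO_DATA
    return float(sum(arr)) / len(arr)


def site_methylation_table(calls: pd.DataFrame, min_reads: int = 3,
                           allele: str | None = None) -> pd.DataFrame:
    """Per-(sample, chrom, pos) methylation levels from deduplicated calls.

    With ``allele`` set ('maternal'/'paternal'), only calls carrying that
    tag contribute.  Sites below ``min_reads`` coverage are omitted.

    Returns ``sample, chrom, pos, n_reads, level``.
    """
    df = calls
    if allele is not None:
        if allele not in ALLELE_TAGS:
            raise ValueError(f"unknown allele tag {allele!r}")
        df = df[df["allele"] == allele]
    if df.empty:
        return pd.DataFrame(columns=["sample", "chrom", "pos", "n_reads", "level"])
    grouped = df.assign(is_meth=(df["state"] == "methylated").astype(int)) \
                .groupby(["sample", "chrom", "pos"], sort=True) \
                .agg(n_reads=("is_meth", "size"), level=("is_meth", "mean")) \
                .reset_index()
    return grouped[grouped["n_reads"] >= min_reads].reset_index(drop=True)


@dataclass
class ICRMethylation:
    """ICR-level methylation summary for one embryo (percentage scale)."""

    icr: str
    sample_id: str
    percent: float  # NaN = no data
    n_sites: int
    allele: str | None = None

    @property
    def has_data(self) -> bool:
        return not math.isnan(self.percent)


def icr_methylation(site_levels: pd.DataFrame, icr: ICRRegion,
                    sample_id: str, allele: str | None = None) -> ICRMethylation:
    """Average qualifying per-site levels inside one ICR for one embryo.

    The mean is unweighted across sites (each CpG counts once regardless
    of coverage) and reported on the 0-100 percentage scale.  Zero
    qualifying sites gives a no-data result, never 0%.
    """
    sub = site_levels[
        (site_levels["sample"] == sample_id)
        & (site_levels["chrom"] == icr.chrom)
        & (site_levels["pos"] >= icr.start)
        & (site_levels["pos"] < icr.end)
    ]
    if sub.empty:
        return ICRMethylation(icr.name, sample_id, NO_DATA, 0, allele)
    return ICRMethylation(
        icr.name, sample_id, float(sub["level"].mean()) * 100.0, len(sub), allele
    )


def allelic_icr_methylation(calls: pd.DataFrame, icr: ICRRegion, sample_id: str,
                            allele: str, min_reads: int = 1) -> ICRMethylation:
    """ICR methylation restricted to one parental allele.

    Allele-tagged coverage is sparse (few reads overlap a strain SNP), so
    the coverage rule relaxes to ``min_reads`` = 1 unique read per CpG.
    """
    if allele not in (MATERNAL, PATERNAL):
        raise ValueError(f"allele must be '{MATERNAL}' or '{PATERNAL}', got {allele!r}")
    levels = site_methylation_table(
        calls[calls["sample"] == sample_id], min_reads=min_reads, allele=allele
    )
    return icr_methylation(levels, icr, sample_id, allele=allele)


def icr_methylation_by_sample(calls: pd.DataFrame, icrs: list[ICRRegion],
                              min_reads: int = 3) -> pd.DataFrame:
    """Total ICR methylation percentages for every (ICR, sample).

    Returns ``icr, sample, percent, n_sites`` with NaN percent where an
    ICR has no qualifying site in a sample.
    """
    levels = site_methylation_table(calls, min_reads=min_reads)
    rows = []
    for icr in icrs:
        for sample in sorted(calls["sample"].unique()):
            m = icr_methylation(levels, icr, sample)
            rows.append({"icr": m.icr, "sample": m.sample_id,
                         "percent": m.percent, "n_sites": m.n_sites})
    return pd.DataFrame(rows, columns=["icr", "sample", "percent", "n_sites"])


def compare_icr_groups(percents: pd.DataFrame, samples: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Group comparisons of per-embryo ICR methylation percentages.

    Two families of tests, per ICR: within each sex, one-way ANOVA with
    Fisher LSD across the three genotypes (pairwise p per genotype pair);
    and within each genotype, a two-tailed Student's t-test between the
    sexes.  Embryos without data for an ICR are dropped; any comparison
    with a group of fewer than two embryos raises.

    ``percents`` needs ``icr, sample, percent``.  Returns a long table
    ``icr, design, group_a, group_b, p_value, stars, test``.
    """
    meta = samples.set_index("sample")
    rows = []
    for icr, sub in percents.dropna(subset=["percent"]).groupby("icr", sort=True):
        sub = sub.join(meta, on="sample")
        # within-sex genotype contrast: ANOVA + Fisher LSD
        for sex, sexdf in sub.groupby("sex", sort=True):
            groups = [sexdf.loc[sexdf["genotype"] == g, "percent"].to_numpy()
                      for g in ("M+Z+", "M-Z+", "M-Z-")]
            sizes = [g.size for g in groups]
            if any(s < 2 for s in sizes):
                raise ValueError(
                    f"{icr}/{sex}: genotype group(s) with <2 embryos {sizes}"
                )
            res = anova_fisher_lsd(groups, alpha=alpha)
            names = ("M+Z+", "M-Z+", "M-Z-")
            for (i, j), p in res.pairwise_p.items():
                rows.append({
                    "icr": icr, "design": f"genotype within {sex}",
                    "group_a": names[i], "group_b": names[j],
                    "p_value": p, "stars": star_label(p),
                    "test": "anova_fisher_lsd",
                    "omnibus_p": res.p_value, "protected": res.protected,
                })
        # within-genotype sex contrast: two-tailed t
        for genotype, gdf in sub.groupby("genotype", sort=True):
            a = gdf.loc[gdf["sex"] == "F", "percent"].to_numpy()
            b = gdf.loc[gdf["sex"] == "M", "percent"].to_numpy()
            if a.size < 2 or b.size < 2:
                raise ValueError(
                    f"{icr}/{genotype}: sex group(s) with <2 embryos "
                    f"(F={a.size}, M={b.size})"
                )
            p = two_tailed_ttest(a, b)
            rows.append({
                "icr": icr, "design": f"sex within {genotype}",
                "group_a": "F", "group_b": "M",
                "p_value": p, "stars": star_label(p),
                "test": "student_t", "omnibus_p": np.nan, "protected": np.nan,
            })
    return pd.DataFrame(rows)


def export_methylation_track(site_levels: pd.DataFrame, sample_id: str) -> str:
    """Render one sample's per-CpG levels as bedGraph text (0-1 scale).

    Each CpG becomes a 1-bp interval (chrom, pos, pos+1, level); lines are
    coordinate-sorted and levels clipped into [0, 1].
    """
    sub = site_levels[site_levels["sample"] == sample_id]
    rows = [
        (str(r.chrom), int(r.pos), int(r.pos) + 1, float(min(max(r.level, 0.0), 1.0)))
        for r in sub.itertuples(index=False)
    ]
    return format_bedgraph(rows)
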