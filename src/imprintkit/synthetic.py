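"""Synthetic data for the 129xDBA Zfp57 hybrid cross.

Generates the three kinds of raw material the downstream analyses consume,
with known ground truth:

* allele-resolved RNA-seq count tables (negative-binomial totals, binomial
  SNP-informative thinning, beta-binomial allelic fractions),
* read-level WGBS-style CpG methylation calls over ICR intervals, with
  allele tags and bisulfite conversion failure,
* bisulfite PCR colony read sets (FASTA) with PCR duplicates for the
  clone-deduplication stage to collapse.

Every generator is driven by one master seed; each stage derives its own
child stream by name, so outputs are reproducible byte-for-byte and
independent across stages.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GENOTYPES,
    MATERNAL,
    PATERNAL,
    SEXES,
    UNASSIGNED,
    ICRRegion,
    child_rng,
    validate_genotype,
    validate_sex,
)

__all__ = [
    "CrossDesign",
    "GeneScenario",
    "ICRScenario",
    "AmpliconScenario",
    "simulate_cross",
    "simulate_allelic_counts",
    "simulate_wgbs_calls",
    "simulate_colony_reads",
]

Group = tuple[str, str]  # (genotype, sex)


@dataclass
class CrossDesign:
    """How many embryos of each (genotype, sex) the simulated cross yields."""

    n_embryos: dict[Group, int]
    seed: int = 0
    maternal_strain_label: str = "129"
    paternal_strain_label: str = "DBA"

    def __post_init__(self) -> None:
        for (genotype, sex), n in self.n_embryos.items():
            validate_genotype(genotype)
            validate_sex(sex)
            if n < 0:
                raise ValueError(f"negative embryo count for ({genotype}, {sex})")
        if sum(self.n_embryos.values()) < 1:
            raise ValueError("cross design must produce at least one embryo")


@dataclass
class GeneScenario:
    """Ground truth for one simulated gene.

    ``paternal_fraction`` maps each (genotype, sex) group to the true
    paternal-allele expression fraction theta; an imprinted gene switching
    to biallelic expression is encoded as theta moving toward 0.5.
    ``allelic_concentration`` is the beta-binomial concentration c: the
    per-sample fraction is drawn Beta(theta*c, (1-theta)*c), so larger c
    means tighter biological replication.  ``math.inf`` pins theta exactly.
    """

    gene_id: str
    gene_length: int
    mean_expression: float
    dispersion: float
    snp_informative_fraction: float
    paternal_fraction: dict[Group, float]
    allelic_concentration: float = 50.0
    #: optional per-group scaling of mean_expression, for simulating
    #: expression-level (rather than allelic) changes; missing groups get 1.0
    expression_multiplier: dict[Group, float] | None = None

    def __post_init__(self) -> None:
        if self.gene_length <= 0:
            raise ValueError(f"{self.gene_id}: gene_length must be positive")
        if self.mean_expression <= 0:
            raise ValueError(f"{self.gene_id}: mean_expression must be positive")
        if self.dispersion < 0:
            raise ValueError(f"{self.gene_id}: dispersion must be non-negative")
        if not 0.0 <= self.snp_informative_fraction <= 1.0:
            raise ValueError(f"{self.gene_id}: snp_informative_fraction in [0,1]")
        if self.allelic_concentration <= 0:
            raise ValueError(f"{self.gene_id}: allelic_concentration must be positive")
        for group, theta in self.paternal_fraction.items():
            if not 0.0 <= theta <= 1.0:
                raise ValueError(f"{self.gene_id}: theta for {group} not in [0,1]")
        if self.expression_multiplier:
            for group, mult in self.expression_multiplier.items():
                if mult <= 0:
                    raise ValueError(
                        f"{self.gene_id}: expression multiplier for {group} "
                        "must be positive"
                    )

    def group_mean_expression(self, group: Group) -> float:
        mult = (self.expression_multiplier or {}).get(group, 1.0)
        return self.mean_expression * mult


@dataclass
class ICRScenario:
    """Ground truth for WGBS read simulation over one ICR.

    ``methylated_allele_level`` is the per-molecule methylation probability
    on the germline-methylated allele for each (genotype, sex) group —
    imprint loss in a mutant group is encoded by dropping this toward the
    ``unmethylated_allele_level`` background.
    """

    icr: ICRRegion
    cpg_positions: list[int]
    methylated_allele_level: dict[Group, float]
    unmethylated_allele_level: dict[Group, float]
    read_depth: float = 30.0
    conversion_failure_rate: float = 0.005
    snp_informative_fraction: float = 0.3

    def __post_init__(self) -> None:
        pos = list(self.cpg_positions)
        if pos and any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"{self.icr.name}: cpg_positions must be strictly increasing")
        for p in pos:
            if not self.icr.contains(p):
                raise ValueError(
                    f"{self.icr.name}: CpG position {p} outside "
                    f"[{self.icr.start}, {self.icr.end})"
                )
        if self.read_depth <= 0:
            raise ValueError(f"{self.icr.name}: read_depth must be positive")
        if not 0.0 <= self.conversion_failure_rate < 1.0:
            raise ValueError(f"{self.icr.name}: conversion_failure_rate in [0,1)")
        if not 0.0 <= self.snp_informative_fraction <= 1.0:
            raise ValueError(f"{self.icr.name}: snp_informative_fraction in [0,1]")


@dataclass
class AmpliconScenario:
    """Ground truth for a bisulfite-PCR colony sequencing experiment."""

    name: str
    amplicon_sequence: str
    true_methylation: float
    conversion_failure_rate: float = 0.005
    n_colonies: int = 30
    pcr_duplication_rate: float = 0.1
    cpg_indices: list[int] = field(default_factory=list)
    non_cpg_c_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amplicon_sequence = self.amplicon_sequence.upper()
        seq = self.amplicon_sequence
        if not self.cpg_indices and not self.non_cpg_c_indices:
            # derive C partitions from the sequence itself
            self.cpg_indices = [
                i for i, b in enumerate(seq)
                if b == "C" and i + 1 < len(seq) and seq[i + 1] == "G"
            ]
            self.non_cpg_c_indices = [
                i for i, b in enumerate(seq)
                if b == "C" and i not in set(self.cpg_indices)
            ]
        overlap = set(self.cpg_indices) & set(self.non_cpg_c_indices)
        if overlap:
            raise ValueError(f"{self.name}: CpG and non-CpG C indices overlap: {overlap}")
        for i in list(self.cpg_indices) + list(self.non_cpg_c_indices):
            if seq[i] != "C":
                raise ValueError(f"{self.name}: position {i} is {seq[i]!r}, not C")
        if not 0.0 <= self.true_methylation <= 1.0:
            raise ValueError(f"{self.name}: true_methylation in [0,1]")
        if not 0.0 <= self.conversion_failure_rate < 1.0:
            raise ValueError(f"{self.name}: conversion_failure_rate in [0,1)")
        if not 0.0 <= self.pcr_duplication_rate < 1.0:
            raise ValueError(f"{self.name}: pcr_duplication_rate in [0,1)")
        if self.n_colonies < 1:
            raise ValueError(f"{self.name}: n_colonies must be >= 1")


def simulate_cross(design: CrossDesign) -> pd.DataFrame:
    """Enumerate the embryos of a cross as a sample metadata table.

    Sample names are deterministic: F1..Fn within female genotypes and
    M1..Mn within male genotypes, numbered across genotypes in the fixed
    order M+Z+, M-Z+, M-Z- (mirroring the F1-F10 / M1-M9 embryo labels the
    study design uses).

    Returns a DataFrame with columns ``sample``, ``genotype``, ``sex``.
    """
    rows = []
    counters = {sex: 0 for sex in SEXES}
    for sex in SEXES:
        for genotype in GENOTYPES:
            n = design.n_embryos.get((genotype, sex), 0)
            for _ in range(n):
                counters[sex] += 1
                rows.append({
                    "sample": f"{sex}{counters[sex]}",
                    "genotype": genotype,
                    "sex": sex,
                })
    if not rows:
        raise ValueError("cross design must produce at least one embryo")
    return pd.DataFrame(rows, columns=["sample", "genotype", "sex"])


def _negbin_totals(rng: np.random.Generator, mean: float, dispersion: float,
                   size: int) -> np.ndarray:
    """NB(mean, dispersion) via gamma-Poisson; dispersion 0 is the Poisson limit."""
    if dispersion == 0.0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam)


def _sample_theta(rng: np.random.Generator, theta: float, concentration: float,
                  size: int) -> np.ndarray:
    """Per-sample allelic fraction: Beta(theta*c, (1-theta)*c), degenerate at edges."""
    if theta in (0.0, 1.0) or math.isinf(concentration):
        return np.full(size, theta)
    return rng.beta(theta * concentration, (1.0 - theta) * concentration, size=size)


def simulate_allelic_counts(scenarios: list[GeneScenario], samples: pd.DataFrame,
                            seed: int) -> pd.DataFrame:
    """Simulate an allele-resolved count table for every gene x sample.

    Per gene and sample: total reads ~ NegBin(mean_expression, dispersion);
    the SNP-informative subset ~ Binomial(total, snp_informative_fraction);
    a per-sample paternal fraction theta* ~ Beta(theta*c, (1-theta)*c); and
    paternal ~ Binomial(informative, theta*), maternal the remainder.

    Returns columns ``gene``, ``sample``, ``maternal_count``,
    ``paternal_count``, ``total_count``.
    """
    groups = list(zip(samples["genotype"], samples["sex"]))
    for sc in scenarios:
        for group in set(groups):
            if group not in sc.paternal_fraction:
                raise ValueError(
                    f"gene {sc.gene_id}: no paternal_fraction entry for group {group}"
                )
    frames = []
    for sc in scenarios:
        rng = child_rng(seed, f"allelic_counts/{sc.gene_id}")
        n = len(samples)
        if sc.expression_multiplier:
            totals = np.array([
                _negbin_totals(rng, sc.group_mean_expression(g), sc.dispersion, 1)[0]
                for g in groups
            ])
        else:
            totals = _negbin_totals(rng, sc.mean_expression, sc.dispersion, n)
        assignable = rng.binomial(totals, sc.snp_informative_fraction)
        thetas = np.array([sc.paternal_fraction[g] for g in groups])
        theta_star = np.empty(n)
        for i, th in enumerate(thetas):
            theta_star[i] = _sample_theta(rng, float(th), sc.allelic_concentration, 1)[0]
        paternal = rng.binomial(assignable, theta_star)
        maternal = assignable - paternal
        frames.append(pd.DataFrame({
            "gene": sc.gene_id,
            "sample": samples["sample"].to_numpy(),
            "maternal_count": maternal,
            "paternal_count": paternal,
            "total_count": totals,
        }))
    return pd.concat(frames, ignore_index=True)


WGBS_CALL_COLUMNS = [
    "sample", "chrom", "pos", "read_id", "allele", "state",
    "read_start", "read_end", "strand",
]


def simulate_wgbs_calls(scenario: ICRScenario, samples: pd.DataFrame,
                        seed: int) -> pd.DataFrame:
    """Simulate read-level CpG methylation calls over one ICR.

    Per sample and CpG site, the number of covering reads is Poisson at
    ``read_depth``.  Each read samples a molecule from one of the two
    parental alleles (50:50); its allele tag is revealed with probability
    ``snp_informative_fraction`` and is otherwise 'unassigned' — an
    untagged molecule still methylates at its true allele's level.  The
    germline-methylated allele (per the ICR's ``germline_origin``)
    methylates at the group's ``methylated_allele_level``, the other at
    ``unmethylated_allele_level``; an unmethylated cytosine still reads
    'methylated' with probability ``conversion_failure_rate`` (bisulfite
    conversion failure).

    Read coordinates and strand are emitted so downstream deduplication by
    (start, end, strand) is exercised; simulated reads are 100 bp, plus
    strand, with distinct starts per read.
    """
    if not scenario.cpg_positions:
        raise ValueError(f"{scenario.icr.name}: no CpG positions to simulate")
    icr = scenario.icr
    meth_allele = icr.germline_origin
    other_allele = PATERNAL if meth_allele == MATERNAL else MATERNAL
    rows: list[dict] = []
    for sample, genotype, sex in zip(samples["sample"], samples["genotype"],
                                     samples["sex"]):
        group = (genotype, sex)
        if group not in scenario.methylated_allele_level:
            raise ValueError(
                f"{icr.name}: no methylated_allele_level entry for group {group}"
            )
        rng = child_rng(seed, f"wgbs/{icr.name}/{sample}")
        hi = scenario.methylated_allele_level[group]
        lo = scenario.unmethylated_allele_level[group]
        read_counter = 0
        for pos in scenario.cpg_positions:
            depth = rng.poisson(scenario.read_depth)
            if depth == 0:
                continue
            is_meth_allele = rng.random(depth) < 0.5
            informative = rng.random(depth) < scenario.snp_informative_fraction
            level = np.where(is_meth_allele, hi, lo)
            methylated = rng.random(depth) < level
            # conversion failure: unmethylated molecules read as methylated
            fails = rng.random(depth) < scenario.conversion_failure_rate
            observed = methylated | (~methylated & fails)
            starts = pos - rng.integers(0, 80, size=depth)
            for k in range(depth):
                read_counter += 1
                if informative[k]:
                    tag = meth_allele if is_meth_allele[k] else other_allele
                else:
                    tag = UNASSIGNED
                rows.append({
                    "sample": sample,
                    "chrom": icr.chrom,
                    "pos": pos,
                    "read_id": f"{sample}.{icr.name}.r{read_counter}",
                    "allele": tag,
                    "state": "methylated" if observed[k] else "unmethylated",
                    "read_start": int(starts[k]),
                    "read_end": int(starts[k]) + 100,
                    "strand": "+",
                })
    return pd.DataFrame(rows, columns=WGBS_CALL_COLUMNS)


def simulate_colony_reads(scenario: AmpliconScenario, seed: int) -> list[tuple[str, str]]:
    """Simulate bisulfite-converted colony reads from one amplicon.

    Each novel molecule methylates each CpG independently with probability
    ``true_methylation``; bisulfite conversion rewrites every unmethylated
    C to T but fails (retains C) with probability
    ``conversion_failure_rate``.  Methylated CpG cytosines are retained.
    After the first read, each subsequent output read is an exact copy of a
    previously emitted molecule with probability ``pcr_duplication_rate``
    (a PCR/cloning duplicate for the dedup stage to collapse).

    Returns ``[(read_id, sequence), ...]`` of length ``n_colonies``,
    writable as FASTA via :func:`imprintkit.io.write_fasta`.
    """
    rng = child_rng(seed, f"colony/{scenario.name}")
    seq = list(scenario.amplicon_sequence)
    cpg = list(scenario.cpg_indices)
    non_cpg = list(scenario.non_cpg_c_indices)
    reads: list[tuple[str, str]] = []
    molecules: list[str] = []
    for i in range(scenario.n_colonies):
        if molecules and rng.random() < scenario.pcr_duplication_rate:
            copied = molecules[rng.integers(0, len(molecules))]
            reads.append((f"{scenario.name}_colony{i + 1}_dup", copied))
            molecules.append(copied)
            continue
        out = seq.copy()
        for idx in cpg:
            methylated = rng.random() < scenario.true_methylation
            if not methylated and rng.random() >= scenario.conversion_failure_rate:
                out[idx] = "T"
        for idx in non_cpg:
            if rng.random() >= scenario.conversion_failure_rate:
                out[idx] = "T"
        read = "".join(out)
        reads.append((f"{scenario.name}_colony{i + 1}", read))
        molecules.append(read)
    return reads
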