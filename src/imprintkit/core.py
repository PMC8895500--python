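"""Shared domain types for the 129xDBA Zfp57 imprinting analyses.

The experimental system is a reciprocal-strain mouse cross: Zfp57-null 129
females mated to Zfp57 heterozygous DBA males, producing E13.5 embryos of
three genotypes — M+Z+ (maternal and zygotic Zfp57 intact), M-Z+ (maternal
lost, zygotic retained) and M-Z- (both lost) — of either sex.  Strain SNPs
make maternal (129) and paternal (DBA) alleles distinguishable in sequence
reads, which is what every analysis in this package leans on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid embryo genotypes.  The cross (Zfp57-/- dam x Zfp57+/- sire) cannot
#: produce an M+Z- embryo, so the enumeration excludes it.
GENOTYPES: tuple[str, ...] = ("M+Z+", "M-Z+", "M-Z-")

#: Valid embryo sexes.
SEXES: tuple[str, ...] = ("F", "M")

#: Parental allele labels used throughout.
MATERNAL = "maternal"
PATERNAL = "paternal"
UNASSIGNED = "unassigned"
CONFLICTING = "conflicting"

ALLELE_TAGS: tuple[str, ...] = (MATERNAL, PATERNAL, UNASSIGNED, CONFLICTING)


class ImprintkitError(Exception):
    """Base class for errors raised by this package."""


def validate_genotype(genotype: str) -> str:
    if genotype not in GENOTYPES:
        raise ValueError(
            f"unknown genotype {genotype!r}; expected one of {GENOTYPES} "
            "(the Zfp57-/- x Zfp57+/- cross cannot produce other genotypes)"
        )
    return genotype


def validate_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return sex


@dataclass(frozen=True)
class SampleMeta:
    """One embryo: identity, Zfp57 genotype and sex."""

    sample_id: str
    genotype: str
    sex: str

    def __post_init__(self) -> None:
        validate_genotype(self.genotype)
        validate_sex(self.sex)


@dataclass(frozen=True)
class AllelicCountRecord:
    """Maternal/paternal read counts for one gene in one sample.

    ``maternal_count`` are reads assigned to the 129 (maternal) allele,
    ``paternal_count`` to the DBA (paternal) allele.
    """

    gene_id: str
    sample_id: str
    maternal_count: int
    paternal_count: int

    def __post_init__(self) -> None:
        if self.maternal_count < 0 or self.paternal_count < 0:
            raise ValueError(
                f"negative allelic count for {self.gene_id}/{self.sample_id}"
            )

    @property
    def total(self) -> int:
        return self.maternal_count + self.paternal_count


@dataclass(frozen=True)
class ICRRegion:
    """A named imprinting control region interval.

    Coordinates are 0-based half-open.  ``germline_origin`` records on which
    parental allele the germline methylation imprint resides (21 of the
    classic mouse ICRs are maternally methylated, 3 paternally).
    """

    name: str
    chrom: str
    start: int
    end: int
    germline_origin: str = MATERNAL

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"ICR {self.name}: start must be < end")
        if self.germline_origin not in (MATERNAL, PATERNAL):
            raise ValueError(
                f"ICR {self.name}: germline_origin must be "
                f"'{MATERNAL}' or '{PATERNAL}'"
            )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class SnpTable:
    """Strain-distinguishing SNPs: position -> (maternal base, paternal base)."""

    entries: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)

    def add(self, chrom: str, pos: int, maternal_base: str, paternal_base: str) -> None:
        maternal_base = maternal_base.upper()
        paternal_base = paternal_base.upper()
        for b in (maternal_base, paternal_base):
            if b not in "ACGT":
                raise ValueError(f"invalid SNP base {b!r} at {chrom}:{pos}")
        if maternal_base == paternal_base:
            raise ValueError(f"SNP at {chrom}:{pos} is not polymorphic")
        self.entries[(chrom, pos)] = (maternal_base, paternal_base)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a deterministic per-stage random generator from a master seed.

    Stage names give each simulation step its own independent stream, so
    adding genes to a scenario never perturbs, say, the WGBS reads.
    """
    stage_key = [ord(c) for c in stage]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *stage_key]))


def child_seed(seed: int, stage: str) -> int:
    """A scalar child seed (below 2**31) derived like :func:`child_rng`."""
    ss = np.random.SeedSequence([int(seed), *[ord(c) for c in stage]])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))
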