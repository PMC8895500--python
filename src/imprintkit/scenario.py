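"""Declarative scenario configuration for the synthetic cross.

A scenario bundles everything one simulated experiment needs: the cross
design (embryo counts per genotype x sex), per-gene allelic-expression
truth, per-ICR methylation truth and bisulfite amplicons.  Scenarios can
be built in Python (see :mod:`imprintkit.presets`) or loaded from a TOML
document with sections ``[design]``, ``[genes.<id>]``, ``[icrs.<id>]``
and ``[amplicons.<id>]``.

Group-keyed mappings (paternal fractions, methylation levels) use keys of
the form ``"M+Z+,F"``; the wildcards ``"*,F"``, ``"M-Z-,*"`` and ``"*"``
fill any groups not named explicitly (most specific key wins).
"""
from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .core import GENOTYPES, SEXES, ICRRegion
from .synthetic import AmpliconScenario, CrossDesign, GeneScenario, ICRScenario

__all__ = ["Scenario", "load_scenario", "parse_group_map", "ALL_GROUPS"]

ALL_GROUPS: list[tuple[str, str]] = [
    (genotype, sex) for genotype in GENOTYPES for sex in SEXES
]


@dataclass
class Scenario:
    """One simulated experiment: design plus per-assay ground truth."""

    design: CrossDesign
    genes: list[GeneScenario] = field(default_factory=list)
    icrs: list[ICRScenario] = field(default_factory=list)
    amplicons: list[AmpliconScenario] = field(default_factory=list)


def parse_group_map(raw: dict[str, float],
                    groups: list[tuple[str, str]] | None = None,
                    ) -> dict[tuple[str, str], float]:
    """Expand a group-keyed TOML mapping, resolving wildcards.

    Precedence: exact ``"G,S"`` > ``"G,*"`` > ``"*,S"`` > ``"*"``.
    """
    groups = groups if groups is not None else ALL_GROUPS
    out: dict[tuple[str, str], float] = {}
    for genotype, sex in groups:
        for key in (f"{genotype},{sex}", f"{genotype},*", f"*,{sex}", "*"):
            if key in raw:
                out[(genotype, sex)] = float(raw[key])
                break
    return out


def _design_from_toml(section: dict) -> CrossDesign:
    n_raw = section.get("n_embryos", {})
    n_embryos: dict[tuple[str, str], int] = {}
    for key, n in n_raw.items():
        genotype, sex = (part.strip() for part in key.split(","))
        n_embryos[(genotype, sex)] = int(n)
    return CrossDesign(
        n_embryos=n_embryos,
        seed=int(section.get("seed", 0)),
        maternal_strain_label=section.get("maternal_strain", "129"),
        paternal_strain_label=section.get("paternal_strain", "DBA"),
    )


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a TOML document."""
    doc = tomllib.loads(Path(path).read_text())
    if "design" not in doc:
        raise ValueError(f"scenario {path}: missing [design] section")
    design = _design_from_toml(doc["design"])
    groups = sorted(design.n_embryos)

    genes = []
    for gene_id, g in doc.get("genes", {}).items():
        genes.append(GeneScenario(
            gene_id=gene_id,
            gene_length=int(g["gene_length"]),
            mean_expression=float(g["mean_expression"]),
            dispersion=float(g.get("dispersion", 0.05)),
            snp_informative_fraction=float(g.get("snp_informative_fraction", 0.3)),
            paternal_fraction=parse_group_map(g["paternal_fraction"], groups),
            allelic_concentration=float(g.get("allelic_concentration", 50.0)),
        ))

    icrs = []
    for name, c in doc.get("icrs", {}).items():
        region = ICRRegion(
            name=name, chrom=c["chrom"], start=int(c["start"]), end=int(c["end"]),
            germline_origin=c.get("germline_origin", "maternal"),
        )
        icrs.append(ICRScenario(
            icr=region,
            cpg_positions=[int(p) for p in c["cpg_positions"]],
            methylated_allele_level=parse_group_map(c["methylated_allele_level"], groups),
            unmethylated_allele_level=parse_group_map(
                c.get("unmethylated_allele_level", {"*": 0.05}), groups),
            read_depth=float(c.get("read_depth", 30.0)),
            conversion_failure_rate=float(c.get("conversion_failure_rate", 0.005)),
            snp_informative_fraction=float(c.get("snp_informative_fraction", 0.3)),
        ))

    amplicons = []
    for name, a in doc.get("amplicons", {}).items():
        amplicons.append(AmpliconScenario(
            name=name,
            amplicon_sequence=a["sequence"],
            true_methylation=float(a["true_methylation"]),
            conversion_failure_rate=float(a.get("conversion_failure_rate", 0.005)),
            n_colonies=int(a.get("n_colonies", 30)),
            pcr_duplication_rate=float(a.get("pcr_duplication_rate", 0.1)),
        ))

    return Scenario(design=design, genes=genes, icrs=icrs, amplicons=amplicons)
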