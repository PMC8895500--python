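"""Ready-made synthetic scenarios.

The presets encode the imprinting patterns the Zfp57 cross exhibits —
partial imprint loss in maternal-only mutants with complete loss in
maternal-zygotic mutants ("snrpn_partial_MZ"), male-specific imprint loss
("rasgrf1_sex_dimorphic") — at parameter values a desk-scale experiment
would use.  Preset numbers are illustrative conventions for testing and
documentation, not measurements of any real locus.

Simulation-scale choices, made once:

* gene expression: mean 500 reads, NB dispersion 0.05, 35% of reads
  SNP-informative, beta-binomial concentration 100 (replicate-to-replicate
  allelic-fraction s.d. about 0.05 at theta = 0.5);
* WGBS: Poisson depth 40 per CpG, 20 CpGs per ICR, 35% allele-taggable
  reads, 0.5% bisulfite conversion failure;
* colonies: 30 per amplicon, 10% PCR duplication.
"""
from __future__ import annotations

from .core import ICRRegion
from .scenario import Scenario
from .synthetic import AmpliconScenario, CrossDesign, GeneScenario, ICRScenario

__all__ = [
    "GENE_DEFAULTS",
    "uniform_fraction",
    "study_design",
    "balanced_design",
    "snrpn_partial_MZ",
    "rasgrf1_sex_dimorphic",
    "synthetic_rasgrf1_amplicon",
    "switch_recovery_scenario",
    "expression_recovery_scenario",
    "sex_dimorphic_icr_scenario",
    "demo_scenario",
]

Group = tuple[str, str]

GENE_DEFAULTS = dict(
    gene_length=2500,
    mean_expression=500.0,
    dispersion=0.05,
    snp_informative_fraction=0.35,
    allelic_concentration=100.0,
)


def study_design(seed: int = 0) -> CrossDesign:
    """The study's embryo layout: F 6/3/4 and M 4/3/3 across M+Z+/M-Z+/M-Z-."""
    return CrossDesign(n_embryos={
        ("M+Z+", "F"): 6, ("M-Z+", "F"): 3, ("M-Z-", "F"): 4,
        ("M+Z+", "M"): 4, ("M-Z+", "M"): 3, ("M-Z-", "M"): 3,
    }, seed=seed)


def balanced_design(n_per_group: int = 4, seed: int = 0) -> CrossDesign:
    """A balanced cross: ``n_per_group`` embryos in each genotype x sex cell."""
    return CrossDesign(n_embryos={
        (genotype, sex): n_per_group
        for genotype in ("M+Z+", "M-Z+", "M-Z-") for sex in ("F", "M")
    }, seed=seed)


def uniform_fraction(theta: float) -> dict[Group, float]:
    """The same fraction/level ``theta`` for every genotype x sex group."""
    return {(g, s): theta
            for g in ("M+Z+", "M-Z+", "M-Z-") for s in ("F", "M")}


def snrpn_partial_MZ(gene_id: str = "Snrpn") -> GeneScenario:
    """Paternally expressed gene: partial switch in M-Z+, complete in M-Z-.

    True paternal fraction 0.98 in controls, 0.74 (halfway) in
    maternal-only mutants, 0.50 (biallelic) in maternal-zygotic mutants,
    in both sexes.
    """
    theta = uniform_fraction(0.98)
    for sex in ("F", "M"):
        theta[("M-Z+", sex)] = 0.74
        theta[("M-Z-", sex)] = 0.50
    return GeneScenario(gene_id=gene_id, paternal_fraction=theta, **GENE_DEFAULTS)


def rasgrf1_sex_dimorphic(name: str = "Rasgrf1_ICR") -> ICRScenario:
    """Paternally methylated ICR losing its imprint only in male M-Z-.

    Methylated-allele level 0.90 everywhere except male M-Z- at 0.10 and
    female M-Z- at 0.50; background allele at 0.05.
    """
    icr = ICRRegion(name=name, chrom="chr9", start=89_774_400, end=89_774_900,
                    germline_origin="paternal")
    hi = uniform_fraction(0.90)
    hi[("M-Z-", "M")] = 0.10
    hi[("M-Z-", "F")] = 0.50
    return ICRScenario(
        icr=icr,
        cpg_positions=[icr.start + 40 + 20 * i for i in range(20)],
        methylated_allele_level=hi,
        unmethylated_allele_level=uniform_fraction(0.05),
        read_depth=40.0,
        conversion_failure_rate=0.005,
        snp_informative_fraction=0.35,
    )


#: 11-bp unit holding one non-CpG C (index 2) and one CpG (index 7);
#: concatenation creates no new CpG at the junctions.
_AMPLICON_UNIT = "TTCATTACGTT"


def synthetic_rasgrf1_amplicon(name: str = "Rasgrf1_amplicon",
                               true_methylation: float = 0.9,
                               n_colonies: int = 30,
                               conversion_failure_rate: float = 0.005,
                               pcr_duplication_rate: float = 0.1,
                               n_units: int = 29) -> AmpliconScenario:
    """A synthetic bisulfite amplicon (319 bp, 29 CpGs by default).

    A stand-in for a real ICR bisulfite-PCR product: a repeated motif
    giving one CpG and one non-CpG cytosine per 11 bp, so both the
    methylation pattern and the unconverted-C fingerprint are exercised.
    """
    return AmpliconScenario(
        name=name,
        amplicon_sequence=_AMPLICON_UNIT * n_units,
        true_methylation=true_methylation,
        conversion_failure_rate=conversion_failure_rate,
        n_colonies=n_colonies,
        pcr_duplication_rate=pcr_duplication_rate,
    )


def switch_recovery_scenario(n_switch: int = 20, n_null: int = 180,
                             seed: int = 0) -> tuple[Scenario, dict[str, bool]]:
    """Allelic-switch recovery benchmark: known switches among null genes.

    ``n_switch`` paternally expressed genes switch from theta 0.98 in
    M+Z+ (through 0.74 in M-Z+) to biallelic 0.50 in M-Z-; ``n_null``
    genes are biallelic (theta 0.50) in every group.  Female embryos at
    the study's 6/3/4 layout.

    Returns the scenario and the per-gene truth map (True = real switch).
    """
    design = CrossDesign(n_embryos={
        ("M+Z+", "F"): 6, ("M-Z+", "F"): 3, ("M-Z-", "F"): 4,
    }, seed=seed)
    genes: list[GeneScenario] = []
    truth: dict[str, bool] = {}
    for i in range(n_switch):
        gid = f"switch{i + 1:03d}"
        genes.append(snrpn_partial_MZ(gid))
        truth[gid] = True
    for i in range(n_null):
        gid = f"null{i + 1:03d}"
        genes.append(GeneScenario(gene_id=gid, paternal_fraction=uniform_fraction(0.5),
                                  **GENE_DEFAULTS))
        truth[gid] = False
    return Scenario(design=design, genes=genes), truth


def expression_recovery_scenario(n_up: int = 8, n_null: int = 40, fold: float = 2.0,
                                 seed: int = 0) -> tuple[Scenario, dict[str, bool]]:
    """Expression-level recovery benchmark.

    ``n_up`` biallelic genes have their expression multiplied by ``fold``
    in M-Z- embryos of both sexes (low NB dispersion 0.02, as for stable
    embryonic expression); ``n_null`` genes are unchanged.  Female embryos
    at the study's 6/3/4 layout.
    """
    design = CrossDesign(n_embryos={
        ("M+Z+", "F"): 6, ("M-Z+", "F"): 3, ("M-Z-", "F"): 4,
    }, seed=seed)
    kwargs = dict(gene_length=2500, mean_expression=400.0, dispersion=0.02,
                  snp_informative_fraction=0.35, allelic_concentration=100.0)
    genes: list[GeneScenario] = []
    truth: dict[str, bool] = {}
    for i in range(n_up):
        gid = f"up{i + 1:03d}"
        genes.append(GeneScenario(
            gene_id=gid, paternal_fraction=uniform_fraction(0.5),
            expression_multiplier={("M-Z-", "F"): fold, ("M-Z-", "M"): fold},
            **kwargs))
        truth[gid] = True
    for i in range(n_null):
        gid = f"flat{i + 1:03d}"
        genes.append(GeneScenario(gene_id=gid, paternal_fraction=uniform_fraction(0.5),
                                  **kwargs))
        truth[gid] = False
    return Scenario(design=design, genes=genes), truth


def sex_dimorphic_icr_scenario(n_per_group: int = 4, seed: int = 0,
                               ) -> tuple[Scenario, ICRScenario]:
    """Methylation recovery benchmark: the sex-dimorphic ICR preset over a
    balanced cross (``n_per_group`` embryos per genotype x sex)."""
    design = balanced_design(n_per_group=n_per_group, seed=seed)
    icr = rasgrf1_sex_dimorphic()
    return Scenario(design=design, icrs=[icr]), icr


def demo_scenario(seed: int = 11) -> Scenario:
    """The default end-to-end demonstration scenario.

    Eight genes spanning the allelic states the study's gene table uses
    (paternal switches, a stable maternal gene, biallelic controls), two
    ICRs (a maternally methylated one losing its imprint in both mutant
    sexes, and the sex-dimorphic paternally methylated preset) and two
    colony amplicons at high versus low methylation.
    """
    genes = [
        snrpn_partial_MZ("Snrpn"),
        snrpn_partial_MZ("Peg3"),
        GeneScenario(gene_id="Zim1", paternal_fraction=uniform_fraction(0.05),
                     **GENE_DEFAULTS),
        GeneScenario(gene_id="Igf2r",
                     paternal_fraction={**uniform_fraction(0.05),
                                        ("M-Z-", "F"): 0.35, ("M-Z-", "M"): 0.35},
                     **GENE_DEFAULTS),
        GeneScenario(gene_id="Bi1", paternal_fraction=uniform_fraction(0.5),
                     **GENE_DEFAULTS),
        GeneScenario(gene_id="Bi2", paternal_fraction=uniform_fraction(0.5),
                     **GENE_DEFAULTS),
        # expression-level change without allelic change: doubled in M-Z-
        GeneScenario(gene_id="Up1", gene_length=2500, mean_expression=400.0,
                     dispersion=0.02, snp_informative_fraction=0.35,
                     paternal_fraction=uniform_fraction(0.5), allelic_concentration=100.0,
                     expression_multiplier={("M-Z-", "F"): 2.0, ("M-Z-", "M"): 2.0}),
        GeneScenario(gene_id="Flat1", gene_length=1500, mean_expression=400.0,
                     dispersion=0.02, snp_informative_fraction=0.35,
                     paternal_fraction=uniform_fraction(0.5), allelic_concentration=100.0),
    ]
    snrpn_icr = ICRScenario(
        icr=ICRRegion(name="Snrpn_ICR", chrom="chr7", start=60_005_000,
                      end=60_005_500, germline_origin="maternal"),
        cpg_positions=[60_005_040 + 20 * i for i in range(20)],
        methylated_allele_level={**uniform_fraction(0.90),
                                 ("M-Z+", "F"): 0.50, ("M-Z+", "M"): 0.50,
                                 ("M-Z-", "F"): 0.10, ("M-Z-", "M"): 0.10},
        unmethylated_allele_level=uniform_fraction(0.05),
        read_depth=40.0,
        snp_informative_fraction=0.35,
    )
    amplicons = [
        synthetic_rasgrf1_amplicon("Rasgrf1_MpZp_M", true_methylation=0.9),
        synthetic_rasgrf1_amplicon("Rasgrf1_MmZm_M", true_methylation=0.1),
    ]
    return Scenario(
        design=study_design(seed=seed),
        genes=genes,
        icrs=[snrpn_icr, rasgrf1_sex_dimorphic()],
        amplicons=amplicons,
    )
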