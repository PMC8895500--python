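# Methods

This note documents the models, conventions and design choices behind
imprintkit, in the spirit of a statistical-software methods appendix.

## The experimental design being modelled

A *Zfp57*⁻/⁻ 129 female crossed to a *Zfp57*⁺/⁻ DBA male yields E13.5
embryos of three genotypes: M⁺Z⁺ (heterozygous offspring of a control
cross, maternal and zygotic *Zfp57* present), M⁻Z⁺ (maternal product
absent, zygotic allele present) and M⁻Z⁻ (both absent). M⁺Z⁻ cannot
arise from this cross and is rejected by the genotype enumeration.
Because the parental strains differ at many SNPs, RNA-seq and WGBS reads
overlapping a SNP can be assigned to the maternal (129) or paternal
(DBA) allele; everything downstream builds on those assignments. The
default embryo layout follows the study design the package emulates:
6/3/4 females and 4/3/3 males across the three genotypes.

## Allelic expression: the P-score

For one gene in one embryo with maternal and paternal read counts M and
P, the P-score is P/(M+P) − 0.5 ∈ [−0.5, +0.5]. It is antisymmetric
under allele swap, +0.5 iff M = 0 and −0.5 iff P = 0. Records with
M + P = 0 are undefined and must be removed first; genes enter the
analysis only when their pooled M+P across the analysis set is strictly
greater than 10. The filter pools over samples and keeps or drops each
gene as a whole; a per-sample variant would silently change the test's
sample sizes per gene, which the pooled rule avoids.

Switch selection, per sex: an omnibus Kruskal–Wallis across the three
genotype groups (mid-ranks, standard tie correction; all-constant input
returns H = 0, p = 1 rather than NaN), plus ΔP = |mean(P-score)ₐ −
mean(P-score)_b| for the named genotype pair. A gene is selected iff
ΔP ≥ 0.1 and p < 0.05. ΔP uses group means, the simplest statistic
consistent with reporting a single group difference; medians are not
offered. No multiple-testing correction is applied by default, matching
the selection rule as stated; the per-gene exact binomial test of
allelic balance (two-sided, null 0.5, minlike convention) is available
as a per-record complement.

Heatmap export provides both the per-sample P-score matrix (columns
ordered M⁺Z⁺, M⁻Z⁺, M⁻Z⁻) and an "intensity difference" view centred on
the reference genotype's mean, since either is a reasonable reading of
an intensity-difference heatmap.

Allelic-state labels from group-mean P-score s̄: |s̄| < 0.1 biallelic;
0.1–0.25 slightly; 0.25–0.4 preferential; ≥ 0.4 monoallelic, signed
maternal/paternal. The verbal state vocabulary has no canonical numeric
cutoffs; these defaults are config-overridable and exported with every
report.

## Expression levels

TPM_g = (count_g/length_g) / Σ_h(count_h/length_h) × 10⁶ per sample;
Σ TPM = 10⁶ whenever any count is positive, and an all-zero sample
yields all-zero TPM with a warning. Gene lengths are supplied in the
input table (annotated transcript-union lengths in real use; scenario
lengths in simulation). Quantifiable genes have pooled raw count > 10
and TPM > 1.0 in at least one embryo — both strict, matching the
"more than" phrasing of the thresholds.

Fold change is log₂ of the ratio of group-mean TPM with pseudocount 0
(a silent group yields ±inf, flagged rather than fatal); the p-value
comes from a Welch t-test on log₂(TPM+1). This is a deliberate,
documented choice of an ordinary two-group test on a
variance-stabilised scale instead of a negative-binomial GLM framework:
the package's claims are parameter recovery on synthetic data, not
replication of any specific published fold-change table, and the Welch
test keeps the differential stage free of tuning. Significance is the
strict conjunction |log₂FC| > threshold (0.5 genotype, 0.3 sex contrast)
and p < 0.05.

Three-group comparisons use one-way ANOVA with Fisher's LSD: pairwise t
statistics on the pooled within-group MSE at N−k df. All pairwise
p-values are reported; a `protected` flag records whether the omnibus F
cleared α, so the caller can apply the classical protected-LSD reading.
Degenerate inputs (zero pooled variance) return F = 0/p = 1 for
identical means and p = 0 for separated means. Two-group comparisons use
the pooled-variance Student t (two-tailed), with the same degenerate
conventions; for k = 2 the LSD pairwise p and the pooled t-test coincide
exactly, which the tests verify.

## WGBS ICR methylation

Coordinates are 0-based half-open throughout; CpG sites are indexed by
the forward-strand C position (reverse-strand G calls should be folded
onto it upstream). Read deduplication collapses reads sharing (sample,
alignment start, end, strand) — the standard bisulfite dedup key; read
uniqueness by ID alone can be selected by pre-deduplicating. Per CpG and
sample, level = methylated/total over unique reads, computed only when
coverage ≥ 3 unique reads; under-covered sites are *excluded*, never
imputed or counted as zero. ICR % is the unweighted mean of qualifying
site levels × 100 — each CpG counts once regardless of coverage, the
literal reading of averaging site levels; a coverage-weighted mean would
let one deep CpG dominate a ragged region. Zero qualifying sites yields
an explicit no-data result.

Allele assignment follows the SNP-split contract: a read votes maternal
or paternal at each strain SNP it covers; unanimous votes tag the read,
mixed votes mark it conflicting, no informative site leaves it
unassigned. Matching is bisulfite-aware and orientation-specific: on a
forward (original-top) read an observed T is compatible with a C allele
base, on a reverse read an observed A with a G allele base, and a base
compatible with both alleles casts no vote (e.g. T at a C/T SNP on a
forward read). Allele-split ICR quantification relaxes the site rule to
≥ 1 unique read, since allele-informative coverage is sparse.

Group comparisons per ICR: ANOVA + Fisher LSD across genotypes within
each sex, Student's t between sexes within each genotype, with stars at
p < 0.05/0.01/0.001 and "ns" otherwise. bedGraph export writes each CpG
as a 1-bp interval with its level clipped to [0, 1], coordinate-sorted.

## Colony bisulfite sequencing

Reads are compared positionally to the amplicon reference (equal length
required; identity computed outside cytosine positions). At CpG
cytosines C reads as methylated and T as unmethylated; any retained
non-CpG C is a conversion failure and joins the clone's fingerprint.
QC: conversion rate ≥ 0.95 and identity ≥ 0.9 (common defaults for this
kind of analysis; both configurable); failing reads are flagged with a
reason, never silently dropped. Clones collapse iff they share both the
CpG pattern and the fingerprint — sequencing differences outside C
positions do not separate clones. The clone-set methylation percentage
counts methylated CpG states over *unique* clones, unweighted by
multiplicity, per the unique-clone formula; a multiplicity-weighted
variant is not the default. Reverse-strand clones are out of scope
(bisulfite PCR primers fix the strand).

## The synthetic generator

Allelic counts: total ~ NegBin(μ, α) via gamma–Poisson (α = 0 is the
Poisson limit); SNP-informative subset ~ Binomial(total, f); per-sample
allelic fraction θ* ~ Beta(θc, (1−θ)c) with concentration c (θ ∈ {0,1}
or c = ∞ pin θ exactly); paternal ~ Binomial(informative, θ*). This is
the standard overdispersed model for allele-specific counts, and θ maps
onto the expected P-score as θ − 0.5. An optional per-group expression
multiplier simulates expression-level changes.

WGBS calls: per CpG and sample, depth ~ Poisson(λ); each read's molecule
comes from one parental allele (50:50) and its allele tag is revealed
with probability f (otherwise "unassigned" — the molecule still
methylates at its true allele's level). The germline-origin allele
methylates at the group's high level, the other at the background; an
unmethylated cytosine still reads methylated with the conversion-failure
probability (default 0.005), applied symmetrically wherever a cytosine
is unmethylated. Expected total ICR level is therefore the equal-weight
allelic mixture (hi + lo)/2 plus a ≤ 0.5-point conversion-failure
offset.

Colony reads: per molecule, CpGs methylate independently at the true
rate; conversion rewrites unmethylated C→T and fails (retains C) with
the same symmetric failure probability at every unmethylated cytosine,
CpG or not; after the first read each output read is an exact copy of an
earlier molecule with the PCR-duplication probability.

Seeding: one master seed; each stage and unit (gene, ICR × sample,
amplicon) derives an independent child stream keyed by name, so outputs
are byte-reproducible and adding one scenario component never perturbs
another.

Default parameter choices, made once as realistic desk-scale settings:
mean 500 reads per gene (NB dispersion 0.05), 35 % SNP-informative
reads, beta-binomial concentration 100 (allelic-fraction s.d. ≈ 0.05 at
θ = 0.5); WGBS depth 40 per CpG over 20 CpGs per ICR; 30 colonies per
amplicon with 10 % duplication. Preset patterns ("snrpn_partial_MZ":
θ 0.98 → 0.74 → 0.50 across genotypes; "rasgrf1_sex_dimorphic":
methylated-allele level 0.90 everywhere but 0.50/0.10 in female/male
M⁻Z⁻) encode the qualitative imprinting behaviours the system exhibits;
their numbers are illustrative conventions, not measurements.

What the generator does *not* emulate: mapping bias and alignment
artefacts, SNP density variation (RNA-level allele tags are drawn
directly rather than via read sequences), chromosome-scale genomes,
non-CpG methylation, and strand-specific coverage asymmetries. Passing
recovery tests therefore demonstrates the correctness and power of the
*analysis machinery* under the stated generative model — not that real
embryo data would yield any particular value.

## Problem sizes and numerical conventions

Recovery suites run at the sizes the package's own benchmarks define:
switch recovery uses 20 switching + 180 null genes over 200 simulated
replicates of a 13-embryo female cohort; methylation recovery uses 100
seeds of a 24-embryo balanced cohort; oracle-agreement suites use 1,000
random small instances per statistic (tolerance 1e-10; exact equality
for recounting oracles). Floating-point output in TSVs is rounded to 10
decimals to make byte-level reproducibility independent of accumulated
representation noise. Statistical wrappers delegate to scipy
(kruskal, binomtest, f_oneway, ttest_ind); Fisher LSD is computed
in-repo from the pooled MSE. The brute-force oracles in the test suite
(explicit ranking, tail enumeration, sums of squares) share no code with
those paths.

## Known limitations

- The differential-expression stage is a Welch t on log₂(TPM+1), not a
  count-model GLM; with few replicates (n ≈ 3) its power profile differs
  from negative-binomial methods, and no multiple-testing correction is
  applied by default (a BH option exists at the API level via
  statsmodels-style post-processing of the returned p-values).
- Colony-read alignment is positional and equal-length only — adequate
  for amplicon-scale data, not a general aligner.
- Allele assignment assumes a correct SNP table; systematic strain
  mapping bias is not modelled or corrected.
- ICR averaging is unweighted across CpGs; regions with very uneven
  coverage will weight sparse sites equally with deep ones (excluded
  sites are reported, so callers can inspect coverage).
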