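# A small custom scenario: 3 embryos per female genotype, one switching
# gene, one ICR losing its imprint in M-Z-, one colony amplicon.
# Group keys are "GENOTYPE,SEX"; "*" wildcards fill unlisted groups.
# Run with: imprintkit simulate --scenario examples/custom_scenario.toml --seed 1 --out out/

[design]
seed = 1

[design.n_embryos]
"M+Z+,F" = 3
"M-Z+,F" = 3
"M-Z-,F" = 3

[genes.Peg3]
gene_length = 2500
mean_expression = 500
dispersion = 0.05
snp_informative_fraction = 0.35
allelic_concentration = 100

[genes.Peg3.paternal_fraction]
"*" = 0.98
"M-Z-,F" = 0.5

[icrs.Peg3_ICR]
chrom = "chr7"
start = 6730000
end = 6730500
germline_origin = "maternal"
cpg_positions = [6730040, 6730060, 6730080, 6730100, 6730120, 6730140, 6730160, 6730180, 6730200, 6730220]
read_depth = 40
snp_informative_fraction = 0.35

[icrs.Peg3_ICR.methylated_allele_level]
"*" = 0.9
"M-Z-,F" = 0.1

[icrs.Peg3_ICR.unmethylated_allele_level]
"*" = 0.05

[amplicons.Peg3_amplicon]
sequence = "TTCATTACGTTTTCATTACGTTTTCATTACGTTTTCATTACGTTTTCATTACGTT"
true_methylation = 0.9
n_colonies = 20
pcr_duplication_rate = 0.1
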