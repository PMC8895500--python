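"""Detect allelic-expression switches with the P-score statistic.

Simulates a female cohort (6 M+Z+, 3 M-Z+, 4 M-Z- embryos) with one
imprinted gene that switches from paternal-only to biallelic expression
when Zfp57 is lost, plus one biallelic control, then runs the switch
selection: Kruskal-Wallis across the three genotypes and the
delta-P >= 0.1 / p < 0.05 rule.
"""
from imprintkit.allelic import (filter_expressed_allelic, pscore_table,
                                select_switched_genes)
from imprintkit.presets import GENE_DEFAULTS, snrpn_partial_MZ, uniform_fraction
from imprintkit.synthetic import (CrossDesign, GeneScenario,
                                  simulate_allelic_counts, simulate_cross)

design = CrossDesign(n_embryos={("M+Z+", "F"): 6, ("M-Z+", "F"): 3,
                                ("M-Z-", "F"): 4})
samples = simulate_cross(design)
genes = [
    snrpn_partial_MZ("Snrpn"),   # true switch: theta 0.98 -> 0.74 -> 0.50
    GeneScenario(gene_id="control", paternal_fraction=uniform_fraction(0.5),
                 **GENE_DEFAULTS),
]
counts = simulate_allelic_counts(genes, samples, seed=42)
scores = pscore_table(filter_expressed_allelic(counts, min_total=10))

results, heatmap, intensity = select_switched_genes(
    scores, samples, sex="F", pair=("M+Z+", "M-Z-"),
    delta_threshold=0.1, alpha=0.05)

print("gene      deltaP    KW p     selected   group means (M+Z+ / M-Z-)")
for r in results:
    print(f"{r.gene_id:9s} {r.delta_pscore:6.3f}  {r.p_value:8.4f}  "
          f"{str(r.selected):8s}  {r.mean_a:+.3f} / {r.mean_b:+.3f}")
print()
print("Per-sample P-scores of the selected gene (0.5 = paternal-only, "
      "0 = biallelic):")
print(heatmap.round(3).to_string())
# The switch gene shows a group-mean P-score near +0.5 in M+Z+ that
# collapses toward 0 in M-Z- (delta-P ~ 0.5, p < 0.05 -> selected); the
# biallelic control stays near 0 everywhere and is not selected.
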