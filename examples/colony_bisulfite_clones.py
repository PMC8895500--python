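"""Colony bisulfite sequencing: clone calling, dedup, methylation percent.

Simulates 30 sequenced bacterial colonies from a synthetic 319-bp
bisulfite amplicon at 90% true methylation with PCR duplicates, calls
each read against the reference, collapses clones indistinguishable by
CpG pattern + unconverted-C fingerprint, and reports the unique-clone
methylation percentage and the lollipop matrix.
"""
from imprintkit.colony import (AmpliconReference, call_clone,
                               clone_set_methylation, compare_clone_methylation,
                               deduplicate_clones, render_lollipop_matrix)
from imprintkit.presets import synthetic_rasgrf1_amplicon
from imprintkit.synthetic import simulate_colony_reads

scenario = synthetic_rasgrf1_amplicon(true_methylation=0.9, n_colonies=30,
                                      pcr_duplication_rate=0.2)
reference = AmpliconReference(name=scenario.name,
                              sequence=scenario.amplicon_sequence)
reads = simulate_colony_reads(scenario, seed=5)
clones = [call_clone(rid, seq, reference) for rid, seq in reads]
unique = deduplicate_clones(clones)

print(f"{len(reads)} colonies -> {sum(c.qc_pass for c in clones)} QC-passing "
      f"-> {len(unique)} unique clones")
print(f"clone-set methylation: {clone_set_methylation(unique):.1f}% "
      f"(true per-molecule rate was 90%)")

matrix = render_lollipop_matrix(unique)
print("\nlollipop matrix, first 5 clones x first 10 CpGs "
      "(1 = methylated circle):")
print(matrix.iloc[:5, :12].to_string(index=False))

# Compare two embryo groups on per-embryo percentages (t-test + stars):
high = [92.0, 88.5, 90.1]   # e.g. three control embryos
low = [12.0, 9.5, 14.2]     # three maternal-zygotic mutant embryos
p, stars = compare_clone_methylation(high, low)
print(f"\ncontrol vs mutant embryos: p={p:.2e} ({stars})")
# Duplicate colonies (identical CpG pattern AND identical retained
# non-CpG C fingerprint) collapse into multiplicities, so the percentage
# counts each distinct molecule once.
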