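"""Genotype-trait association with compact letter displays.

Simulates the default cohort (176 birds, 133 F / 43 M) where the hom-ref
genotype at locus g.57337C>A truly depresses 16-week live weight, fits
Y = mu + genotype + sex + error, and prints the trait-table row with
dual-alpha letters: genotypes sharing no lowercase letter differ at
p < 0.05, sharing no uppercase letter at p < 0.01.
"""

from snptrait import TraitModelSpec, analyze_trait, paper_preset, simulate_cohort

spec = paper_preset(seed=42)
cohort = simulate_cohort(spec)
locus = spec.loci[0].locus

summary = analyze_trait(cohort.records, TraitModelSpec("live_weight_16w", locus))

print(f"live weight at 16 weeks (g) by genotype at {locus.id}:")
for level in summary.genotype_levels:
    label = locus.genotype_label(level)
    print(f"  {label:>2} (n={summary.ns[level]:3d}): {summary.cell(level)}")
print(f"genotype F = {summary.genotype_F:.2f}, p = {summary.genotype_p:.4f}")
print()
print(
    "Each cell is the raw group mean ± SD with significance letters from\n"
    "model-adjusted pairwise contrasts (Fisher's LSD on the pooled MSE);\n"
    "'a' marks the highest mean, and genotypes sharing a letter do not\n"
    "differ at that alpha. The simulated truth puts the CC genotype\n"
    "~80-95 g below the others — an effect this unbalanced design detects\n"
    "in some cohorts and misses in others, which is exactly what the\n"
    "letters report."
)
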