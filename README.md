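# snptrait

Candidate-gene SNP analysis for livestock association studies: marker
diversity statistics, genotype–trait association under a fixed-effects
linear model with compact letter displays, and 2^−ΔΔCt relative gene
expression. Written for quantitative-genetics workflows of the kind used
when a handful of SNPs in a candidate growth or fat-deposition gene are
tested against slaughter and growth traits in a modest pedigreed poultry
cohort.

## What it computes

**Marker diversity** (per biallelic locus, from genotype counts):

- allele frequencies by direct counting, `p = (2·n_hom + n_het) / 2N`
- average heterozygosity `H = 1 − Σ pᵢ²`
- polymorphism information content
  `PIC = 1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²` (graded <0.25 low,
  0.25–0.5 moderate, >0.5 high)
- effective allele number `Ne = 1 / Σ pᵢ²`
- Hardy–Weinberg χ² goodness-of-fit over all three genotype classes
  against `N·(p², 2pq, q²)`, with selectable degrees of freedom
  (`paper`: df = 2; `standard`: df = 1)

**Trait association**: per trait × locus, ordinary least squares on

    Y_ijk = μ + G_j + S_k + e_ijk

(genotype + sex, no interaction), partial (Type-III) F test for genotype in
the unbalanced design, model-adjusted pairwise contrasts (Fisher's LSD
default; Tukey HSD and Bonferroni available), and dual-alpha compact letter
displays: lower-case letters at α = 0.05, upper-case at α = 0.01, two
genotypes sharing a letter iff they do not differ at that α.

**Expression**: Livak 2^−ΔΔCt relative quantification against a reference
gene and calibrator group, Student's (or Welch's) t-tests on the ΔCt scale
with `*` / `**` significance marks.

**Synthetic cohorts**: because raw cohorts of this kind are rarely
deposited, a seeded generator produces genotypes with a controllable
inbreeding coefficient (heterozygote deficit), traits from the additive
model above, and qPCR plates with known fold changes — ground truth for
every pipeline stage.

## Worked example

`examples/marker_diversity.py` rebuilds a published 176-bird genotype table
and prints the per-locus summary:

```
      locus genotype   N  genotypic_freq allele allelic_freq   chi2      p      H    PIC     Ne polymorphism_class
 g.57337C>A       AA  18           0.102      A        0.236  11.81  0.003   0.36  0.295  1.563           moderate
                  AC  47           0.267      C        0.764
                  CC 111           0.631
 g.64757T>G       TT  21           0.119      T        0.261  12.29  0.002  0.386  0.312  1.629           moderate
 ...
```

Reading the first row: allele A has frequency 0.236; the locus is
moderately informative (PIC 0.295); and χ² = 11.81 (p = 0.003 at df 2)
flags a heterozygote deficit relative to Hardy–Weinberg proportions.

The other examples (`trait_association.py`, `relative_expression.py`,
`simulate_cohort.py`) each simulate a cohort, run one capability and
explain the printed numbers. A thin CLI wraps the same calls:

```bash
snptrait simulate --seed 1 --out-dir out/
snptrait diversity out/genotypes.csv --out-dir out/
snptrait assoc out/genotypes.csv out/traits.csv --out-dir out/
snptrait expression out/expression.csv --calibrator W1 --out-dir out/
```

Every command writes a rounded display TSV plus a full-precision JSON;
validation problems exit with code 2.

## Layout

- `src/snptrait/genotypes.py` — loci, samples, call canonicalization, tabulation
- `src/snptrait/diversity.py` — H, PIC, Ne, HWE χ²
- `src/snptrait/association.py` — model fit, contrasts, letter displays
- `src/snptrait/expression.py` — 2^−ΔΔCt and t-tests
- `src/snptrait/synthetic.py` — cohort/qPCR simulators
- `src/snptrait/io.py`, `reports.py`, `cli.py` — formats, rendering, CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
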