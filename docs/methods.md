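# Methods

## Scope and data model

The package analyses biallelic candidate-gene SNPs in a single cohort.
Genotypes arrive as two-letter calls ("CA"), are canonicalized to unordered
allele pairs (so "CA" and "AC" are one heterozygote class), and are
validated against each locus's declared reference/alternative alleles.
Missing calls are dropped per locus (complete-case per locus), so sample
sizes may differ across loci and traits — the situation real trait tables
show. All statistics are computed at full double precision; rounding
(half-away-from-zero) happens only in the report-rendering layer, with a
parallel JSON layer that keeps full precision.

## Diversity statistics

For allele frequencies p_i obtained by direct allele counting,

- average heterozygosity `H = 1 − Σ p_i²` — the expected heterozygote
  frequency under random mating;
- polymorphism information content
  `PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²` — marker informativeness for
  linkage/association work, graded low (<0.25), moderate (0.25–0.5),
  high (>0.5);
- effective allele number `Ne = 1 / Σ p_i²` — the equifrequent allele count
  with the same homozygosity.

The formulas are written over n alleles although v1 inputs are biallelic.
Identities used as test invariants: `Ne · Σ p_i² = 1` and `PIC ≤ H` (the
subtracted pairwise term is non-negative); all three statistics are
invariant to which allele is labelled reference.

## Hardy–Weinberg test

Observed genotype counts are tested against expected counts
`N·(p², 2pq, q²)` with p estimated from the same counts, as a χ²
goodness-of-fit over **all three** classes — a class with zero observed
count still contributes its expected count to the sum. No continuity
correction and no exact test are applied.

Degrees of freedom are configurable. `df_mode="paper"` uses df = 2 (three
classes minus one), the convention some published marker tables follow;
`df_mode="standard"` uses df = 1, the conventional choice once the allele
frequency is estimated from the data. df = 2 is conservative: under a
simulated exact-equilibrium null the df = 1 rejection rate sits at the
nominal 5% while df = 2 rejects less often (both checked in the acceptance
suite). The default is `paper` for display parity with such tables;
`standard` is the statistically conventional option.

A monomorphic locus (p ∈ {0, 1}) has no testable departure; χ² is defined
as 0 with a `monomorphic` flag rather than dividing by a zero expectation.

### Non-reproduced display cells

Published marker tables of this kind are not always internally consistent
about rounding. Recomputing one such table from its printed counts
reproduces every cell except four: one locus's H/PIC (printed 0.091/0.087,
which arise only if allele frequencies are pre-rounded to 3 decimals; full
precision gives 0.092/0.088) and two p-values (printed 0.798/0.744 where
full precision gives 0.797/0.774). This package never pre-rounds inside a
computation; the tests pin the full-precision display values and note the
printed variants as transcription/rounding artifacts.

## Trait association model

Each trait × locus pair is fitted by OLS:

    Y_ijk = μ + G_j + S_k + e_ijk

with genotype (up to three classes) and sex (F reference) as fixed factors
and no interaction. Week-by-week body weights are treated as separate
traits; no longitudinal correlation is modelled. The genotype test is the
partial ("each-term-last") F — the full model's residual sum of squares
against the model with genotype dropped — which is the Type-III test
appropriate for unbalanced designs; for a no-interaction model it is
invariant to factor coding, and in the balanced limit it equals the
classical two-way ANOVA F (checked against `statsmodels.anova_lm` as an
independent oracle).

Degenerate designs fail loudly: a factor with one observed level, a
rank-deficient design, or fewer observations than parameters raises a
`DegenerateDesignError` naming the problem.

### Pairwise comparisons and letters

Pairwise genotype differences are model-adjusted contrasts
`coef(a) − coef(b)` with standard errors from the coefficient covariance
(pooled MSE, residual df). Adjustments: Fisher's LSD (none, the default —
the procedure that most readily yields the a/ab/b patterns such tables
print; the exact SPSS procedure behind published tables is typically
unstated), Bonferroni (`min(1, m·p)`), and Tukey HSD via the studentized
range distribution.

Letters are assigned by insert-and-absorb: start with one column holding
all groups; for each significant pair, split every column containing both;
absorb columns that duplicate or are subsets of another. Groups are ordered
by descending observed mean (ties broken by canonical genotype order:
hom-ref, het, hom-alt) so 'a'/'A' always marks the highest mean. The
construction guarantees the display invariant — two groups share a letter
iff their adjusted p ≥ α — which the acceptance suite verifies exactly on
500 random p-matrices. Lower-case letters are rendered at α = 0.05 and
upper-case at α = 0.01.

Summaries print **raw** group means ± SD (ddof = 1) with group n, while the
letters come from the model-based comparisons. This mixed convention is
deliberate: the SD column of a trait table describes raw dispersion, the
letters describe adjusted inference.

## Relative expression (2^−ΔΔCt)

Technical replicates are averaged on the Ct scale; then
`ΔCt = Ct_target − Ct_reference` per sample,
`ΔΔCt = ΔCt − mean(ΔCt over the calibrator group)`, and
`fold = 2^−ΔΔCt`, so the calibrator's geometric-mean fold is 1 by
construction. Amplification efficiency is assumed exactly 2 per cycle for
both genes (no Pfaffl correction). Group tests default to Student's
pooled-variance t on the ΔCt scale — fold changes are log-normal, so ΔCt is
the better-behaved scale, and p on that scale is invariant to the
calibrator choice — with `scale="fold"` and Welch's test available.
Significance marks follow the usual figure legend: `*` for p < 0.05, `**`
for p < 0.01.

## Synthetic cohorts

The generator exists because raw cohorts behind candidate-gene tables are
rarely deposited; it emulates their statistical structure with known ground
truth.

- **Genotypes**: class probabilities `(p² + Fpq, 2pq(1−F), q² + Fpq)` with
  a single inbreeding coefficient F parameterizing the HWE departure;
  positive F reproduces the heterozygote deficit real panels show. Richer
  disequilibrium models are out of scope.
- **Traits**: `Y = μ + g[genotype] + s[sex] + N(0, σ²)`, iid across birds —
  the sampling counterpart of the fitted model. Residuals are Gaussian, as
  the linear model implicitly assumes.
- **qPCR**: reference Ct ~ N(μ_ref, σ_ct²); target Ct shifted by
  −log2(fold) per group, so recovered log2 fold changes are unbiased.

The `paper_preset` cohort has 176 birds (133 F, 43 M), four loci at
reference-allele frequencies 0.764 (C), 0.261 (T), 0.952 (G), 0.949 (G)
with F = 0.26 / 0.28 at the two moderately polymorphic loci (matching their
heterozygote deficits) and 0 at the two near-monomorphic ones, and five
gram-scale traits (e.g. 16-week live weight μ ≈ 1360 g, σ ≈ 230 g, genotype
effects 0/80/95 g, sex effect 180 g). True effect sizes are unknowable
without raw data; these are chosen once to be realistic for a 16-week
dual-purpose chicken and to qualitatively match published letter patterns
(hom-ref lowest at the first locus), not to reproduce any printed mean.
What passing simulation tests show is that the machinery recovers known
parameters under the model's own assumptions; they cannot certify
robustness to non-Gaussian residuals, genotype×sex interaction, pedigree
structure or longitudinal correlation, none of which the generator emulates.

## Numerical and design choices

- Frequencies are plain double-precision ratios of integer counts; no
  rational arithmetic is needed at these magnitudes (denominators ≤ 2N).
- Display rounding is half-away-from-zero (`decimal.ROUND_HALF_UP`), the
  convention statistical tables use, not banker's rounding.
- Letter-order ties in observed means break by canonical genotype order for
  determinism; simulation seeds flow through `numpy.random.default_rng`
  only, making every generated table byte-reproducible.
- Monte-Carlo problem sizes in the test suite (e.g. 500-replicate parameter
  recovery, 1000-replicate null-uniformity, 2000-replicate calibration
  checks at n = 176 or n = 6/group) were sized so each check has enough
  resolution for a 3-standard-error or KS criterion while the whole suite
  stays comfortably interactive.

## Known limitations

- Biallelic loci only (the formulas generalize; the types do not yet).
- No phasing, linkage, haplotype or multi-locus statistics; no random
  effects or repeated-measures models.
- The HWE χ² is asymptotic; with a near-monomorphic locus the smallest
  expected class can fall below 1, where the exact test would be
  preferable (deliberately not implemented to keep display parity with the
  tables this mirrors).
- VCF import handles biallelic SNP records with GT only; sex must come from
  a sidecar table.
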