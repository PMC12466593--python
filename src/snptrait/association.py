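"""Genotype-trait association under a two-factor fixed-effects linear model.

Each trait x locus combination is analysed with the additive model

    Y_ijk = mu + G_j + S_k + e_ijk

where G is the genotype class at a biallelic locus (hom-ref / het /
hom-alt), S is sex (F reference), and e is iid Gaussian error. The design
is typically unbalanced, so the genotype test uses the partial
(Type-III / each-term-last) F statistic: the residual sum of squares of the
full model is compared against the model with the genotype factor dropped.
Without an interaction term this partial test does not depend on the factor
coding.

Pairwise genotype comparisons are model-adjusted contrasts on the pooled
residual mean square. Three adjustment flavours are offered: Fisher's LSD
(unadjusted, the default), Tukey HSD (studentized range) and Bonferroni.
Comparisons are rendered as compact letter displays: group means sorted in
descending order get letters (insert-and-absorb) such that two genotypes
share a letter if and only if their difference is non-significant at the
chosen alpha — lower case at alpha = 0.05, upper case at alpha = 0.01 by
reporting convention.

Summaries print the raw per-genotype mean +/- SD with sample size; letters
come from the model-based comparisons. This mixed convention (raw
dispersion, adjusted inference) is the one quantitative-genetics trait
tables conventionally use.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDesignError, ValidationError
from .genotypes import GENOTYPE_CLASSES, Locus, SampleRecord

MC_METHODS = ("lsd", "tukey", "bonferroni")


@dataclass(frozen=True)
class TraitModelSpec:
    """Which trait and locus to model; factors are fixed as [genotype, sex]."""

    trait_name: str
    locus: Locus


@dataclass
class ModelFit:
    """OLS fit of trait ~ genotype + sex with partial genotype F test."""

    spec: TraitModelSpec
    coefficients: dict[str, float]
    cov_params: np.ndarray
    param_names: list[str]
    residual_df: int
    mse: float
    genotype_F: float
    genotype_p: float
    genotype_levels: list[str]           # canonical order, observed levels only
    group_ns: dict[str, int]
    group_means: dict[str, float]        # raw observed means, grams
    group_sds: dict[str, float]          # raw observed SDs (ddof=1), grams
    n_used: int

    def genotype_coefficient(self, level: str) -> float:
        """Model coefficient of a genotype level (reference level = 0)."""
        name = f"genotype[{level}]"
        return self.coefficients.get(name, 0.0)


@dataclass(frozen=True)
class PairwiseComparison:
    """Adjusted mean difference between two genotype classes."""

    pair: tuple[str, str]
    diff: float
    se: float
    t: float
    df: int
    p_raw: float
    p_adj: float
    method: str


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display at one alpha level."""

    alpha: float
    case: str                      # "lower" | "upper"
    letters: dict[str, str]        # genotype class -> letter string


@dataclass(frozen=True)
class GenotypeTraitSummary:
    """One table row: per-genotype n, raw mean +/- SD, significance letters."""

    trait_name: str
    locus: Locus
    genotype_levels: tuple[str, ...]
    ns: Mapping[str, int]
    means: Mapping[str, float]
    sds: Mapping[str, float]
    letters_low: Mapping[str, str]     # alpha = 0.05, lower case
    letters_high: Mapping[str, str]    # alpha = 0.01, upper case
    genotype_F: float
    genotype_p: float

    def cell(self, level: str, decimals: int = 2) -> str:
        """Render one genotype cell as ``mean +/- SD ^letters^``."""
        letters = self.letters_high[level] + self.letters_low[level]
        return (
            f"{self.means[level]:.{decimals}f} ± {self.sds[level]:.{decimals}f}"
            f" ^{letters}^"
        )


def _complete_cases(
    records: Iterable[SampleRecord], spec: TraitModelSpec
) -> tuple[list[str], list[str], np.ndarray]:
    """Extract (genotype class, sex, trait) for records complete in all three."""
    genos: list[str] = []
    sexes: list[str] = []
    ys: list[float] = []
    for rec in records:
        klass = rec.genotype_class(spec.locus)
        y = rec.traits.get(spec.trait_name)
        if klass is None or y is None:
            continue
        genos.append(klass)
        sexes.append(rec.sex)
        ys.append(float(y))
    return genos, sexes, np.asarray(ys, dtype=float)


def fit_trait_model(records: Iterable[SampleRecord], spec: TraitModelSpec) -> ModelFit:
    """Fit Y = mu + genotype + sex + error by OLS on complete cases.

    The genotype F statistic is the partial (each-term-last) test of the
    genotype factor given sex, appropriate for the unbalanced designs these
    cohorts have.
    """
    genos, sexes, y = _complete_cases(records, spec)
    n = y.size
    levels = [g for g in GENOTYPE_CLASSES if g in genos]
    if len(levels) < 2:
        raise DegenerateDesignError(
            f"factor 'genotype' at locus {spec.locus.id!r} has "
            f"{len(levels)} observed level(s); need at least 2"
        )
    sex_levels = sorted(set(sexes))
    if len(sex_levels) < 2:
        raise DegenerateDesignError(
            f"factor 'sex' has a single observed level {sex_levels!r}"
        )

    # treatment coding: first canonical genotype level and sex F are references
    geno_dummies = {
        f"genotype[{lv}]": np.array([1.0 if g == lv else 0.0 for g in genos])
        for lv in levels[1:]
    }
    sex_col = np.array([1.0 if s == "M" else 0.0 for s in sexes])
    names = ["Intercept", *geno_dummies, "sex[M]"]
    X = np.column_stack([np.ones(n), *geno_dummies.values(), sex_col])
    if n <= X.shape[1]:
        raise DegenerateDesignError(
            f"{n} complete cases cannot identify {X.shape[1]} parameters"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")

    full = sm.OLS(y, X).fit()
    reduced_cols = [0, X.shape[1] - 1]  # intercept + sex
    reduced = sm.OLS(y, X[:, reduced_cols]).fit()
    q = len(levels) - 1
    rss_f, rss_r = full.ssr, reduced.ssr
    df_resid = int(full.df_resid)
    mse = rss_f / df_resid
    if mse > 0:
        F = ((rss_r - rss_f) / q) / mse
        p = float(stats.f.sf(F, q, df_resid))
    else:  # perfect fit
        F, p = math.inf, 0.0

    garr = np.asarray(genos)
    group_ns = {lv: int((garr == lv).sum()) for lv in levels}
    group_means = {lv: float(y[garr == lv].mean()) for lv in levels}
    group_sds = {
        lv: float(y[garr == lv].std(ddof=1)) if group_ns[lv] > 1 else 0.0
        for lv in levels
    }
    return ModelFit(
        spec=spec,
        coefficients=dict(zip(names, full.params)),
        cov_params=np.asarray(full.cov_params()),
        param_names=names,
        residual_df=df_resid,
        mse=float(mse),
        genotype_F=float(F),
        genotype_p=p,
        genotype_levels=levels,
        group_ns=group_ns,
        group_means=group_means,
        group_sds=group_sds,
        n_used=n,
    )


def pairwise_genotype_comparisons(
    fit: ModelFit, method: str = "lsd"
) -> list[PairwiseComparison]:
    """All pairwise genotype contrasts on the pooled model MSE.

    The difference between levels a and b is the model-adjusted contrast
    ``coef(a) - coef(b)`` with standard error from the coefficient
    covariance; two-sided p from the t distribution at the residual df.
    ``lsd`` leaves p unadjusted, ``bonferroni`` multiplies by the number of
    pairs, ``tukey`` uses the studentized range distribution.
    """
    if method not in MC_METHODS:
        raise ValidationError(f"unknown multiple-comparison method {method!r}")
    levels = fit.genotype_levels
    k = len(levels)
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    out: list[PairwiseComparison] = []
    for a, b in pairs:
        c = np.zeros(len(fit.param_names))
        name_a, name_b = f"genotype[{a}]", f"genotype[{b}]"
        if name_a in fit.param_names:
            c[fit.param_names.index(name_a)] = 1.0
        if name_b in fit.param_names:
            c[fit.param_names.index(name_b)] = -1.0
        diff = fit.genotype_coefficient(a) - fit.genotype_coefficient(b)
        se = float(np.sqrt(c @ fit.cov_params @ c))
        if se == 0.0:
            t = math.inf if diff != 0 else 0.0
            p_raw = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p_raw = float(2.0 * stats.t.sf(abs(t), fit.residual_df))
        if method == "lsd":
            p_adj = p_raw
        elif method == "bonferroni":
            p_adj = min(1.0, m * p_raw)
        else:  # tukey
            p_adj = float(
                stats.studentized_range.sf(math.sqrt(2.0) * abs(t), k, fit.residual_df)
            )
        out.append(
            PairwiseComparison(
                pair=(a, b), diff=diff, se=se, t=t, df=fit.residual_df,
                p_raw=p_raw, p_adj=p_adj, method=method,
            )
        )
    return out


def compact_letter_display(
    comparisons: Sequence[PairwiseComparison],
    observed_means: Mapping[str, float],
    alpha: float,
    case: str = "lower",
) -> LetterDisplay:
    """Assign significance letters by the insert-and-absorb algorithm.

    Groups are ordered by descending observed mean (ties broken by canonical
    genotype order) so the letter 'a'/'A' marks the highest mean. The
    resulting display satisfies: two groups share at least one letter iff
    their adjusted pairwise p is >= alpha.
    """
    if case not in ("lower", "upper"):
        raise ValueError("case must be 'lower' or 'upper'")
    groups = sorted(
        observed_means,
        key=lambda g: (-observed_means[g], _canonical_rank(g)),
    )
    pmap = {frozenset(c.pair): c.p_adj for c in comparisons}
    needed = {frozenset(p) for p in itertools.combinations(groups, 2)}
    missing = needed - set(pmap)
    if missing:
        raise ValidationError(
            f"comparison set does not cover all genotype pairs; missing {sorted(tuple(sorted(m)) for m in missing)}"
        )

    # insert-and-absorb: split every column containing a significant pair,
    # then drop columns that are subsets of (or duplicate) another
    columns: list[set[str]] = [set(groups)]
    for pair, p in pmap.items():
        if p >= alpha:
            continue
        i, j = tuple(pair)
        nxt: list[set[str]] = []
        for col in columns:
            if i in col and j in col:
                nxt.append(col - {j})
                nxt.append(col - {i})
            else:
                nxt.append(col)
        columns = _absorb(nxt)

    # letters ordered by the best-ranked member of each column
    rank = {g: idx for idx, g in enumerate(groups)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for idx, col in enumerate(columns):
        letter = alphabet[idx] if case == "lower" else alphabet[idx].upper()
        for g in col:
            letters[g].append(letter)
    return LetterDisplay(
        alpha=alpha, case=case,
        letters={g: "".join(sorted(ls)) for g, ls in letters.items()},
    )


def _canonical_rank(level: str) -> int:
    try:
        return GENOTYPE_CLASSES.index(level)
    except ValueError:
        return len(GENOTYPE_CLASSES)


def _absorb(columns: list[set[str]]) -> list[set[str]]:
    """Drop empty columns, duplicates, and columns contained in another."""
    kept: list[set[str]] = []
    for col in columns:
        if not col or any(col <= other for other in kept):
            continue
        kept = [other for other in kept if not (other < col)]
        kept.append(col)
    return kept


def summarize_trait_by_genotype(
    fit: ModelFit,
    display_low: LetterDisplay,
    display_high: LetterDisplay,
) -> GenotypeTraitSummary:
    """Assemble the trait-table row: raw mean +/- SD per genotype + letters."""
    return GenotypeTraitSummary(
        trait_name=fit.spec.trait_name,
        locus=fit.spec.locus,
        genotype_levels=tuple(fit.genotype_levels),
        ns=dict(fit.group_ns),
        means=dict(fit.group_means),
        sds=dict(fit.group_sds),
        letters_low=dict(display_low.letters),
        letters_high=dict(display_high.letters),
        genotype_F=fit.genotype_F,
        genotype_p=fit.genotype_p,
    )


def analyze_trait(
    records: Iterable[SampleRecord],
    spec: TraitModelSpec,
    method: str = "lsd",
    alpha: float = 0.05,
    alpha_high: float = 0.01,
) -> GenotypeTraitSummary:
    """One-stop trait analysis: fit, pairwise comparisons, dual-alpha letters."""
    recs = list(records)
    fit = fit_trait_model(recs, spec)
    comps = pairwise_genotype_comparisons(fit, method=method)
    low = compact_letter_display(comps, fit.group_means, alpha, "lower")
    high = compact_letter_display(comps, fit.group_means, alpha_high, "upper")
    return summarize_trait_by_genotype(fit, low, high)
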