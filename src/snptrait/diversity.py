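"""Marker informativeness statistics and the Hardy-Weinberg chi-square test.

For an allele frequency spectrum {p_i} the module computes

* average (expected) heterozygosity  H  = 1 - sum p_i^2,
* polymorphism information content   PIC = 1 - sum p_i^2
                                           - sum_{i<j} 2 p_i^2 p_j^2,
* effective number of alleles        Ne = 1 / sum p_i^2,

and tests observed genotype counts against Hardy-Weinberg expectations
N*(p^2, 2pq, q^2) with a chi-square goodness-of-fit over all three genotype
classes, including a class observed zero times. The formulas are written
over n alleles even though v1 inputs are biallelic, so a multi-allelic
extension needs no change here.

The degrees of freedom of the HWE test are configurable: ``df_mode="paper"``
uses df = 2 (three classes minus one, ignoring the estimated allele
frequency) while ``df_mode="standard"`` uses the conventional df = 1 for a
biallelic marker (one frequency estimated from the data). df = 2 is
conservative; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import EmptyLocusError
from .genotypes import (
    AlleleFrequencySpectrum,
    GenotypeCountTable,
    Locus,
    allele_frequencies,
)

DF_MODES = ("paper", "standard")

#: PIC bands used to grade marker informativeness.
PIC_LOW, PIC_HIGH = 0.25, 0.5


def heterozygosity(spectrum: AlleleFrequencySpectrum) -> float:
    """Average heterozygosity H = 1 - sum p_i^2."""
    return 1.0 - sum(p * p for p in spectrum.values)


def pic(spectrum: AlleleFrequencySpectrum) -> float:
    """Polymorphism information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2. For two alleles this
    reduces to 2pq - 2 p^2 q^2.
    """
    ps = spectrum.values
    hom = sum(p * p for p in ps)
    pair = 0.0
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            pair += 2.0 * ps[i] * ps[i] * ps[j] * ps[j]
    return 1.0 - hom - pair


def effective_allele_number(spectrum: AlleleFrequencySpectrum) -> float:
    """Effective number of alleles Ne = 1 / sum p_i^2."""
    return 1.0 / sum(p * p for p in spectrum.values)


def classify_polymorphism(pic_value: float) -> str:
    """Grade a PIC value: < 0.25 low, 0.25-0.5 moderate, > 0.5 high."""
    if pic_value < PIC_LOW:
        return "low"
    if pic_value > PIC_HIGH:
        return "high"
    return "moderate"


@dataclass(frozen=True)
class DiversityStats:
    """The per-locus diversity summary: H, PIC, Ne and the PIC grade."""

    locus: Locus
    H: float
    PIC: float
    Ne: float
    polymorphism_class: str


@dataclass(frozen=True)
class HWETestResult:
    """Chi-square goodness-of-fit of genotype counts to HWE proportions."""

    locus: Locus
    expected_counts: tuple[float, float, float]
    chi2: float
    df: int
    p_value: float
    monomorphic: bool = False


def diversity_stats(spectrum: AlleleFrequencySpectrum) -> DiversityStats:
    """Bundle H, PIC and Ne for one spectrum."""
    p = pic(spectrum)
    return DiversityStats(
        locus=spectrum.locus,
        H=heterozygosity(spectrum),
        PIC=p,
        Ne=effective_allele_number(spectrum),
        polymorphism_class=classify_polymorphism(p),
    )


def hwe_test(counts: GenotypeCountTable, df_mode: str = "paper") -> HWETestResult:
    """Hardy-Weinberg chi-square goodness-of-fit for one biallelic locus.

    Expected counts are N*(p^2, 2pq, q^2) with p the reference-allele
    frequency computed at full precision from the same counts. All three
    genotype classes enter the chi-square sum, a zero observed count
    included. A monomorphic locus (p in {0, 1}) has no testable departure:
    chi2 is defined as 0 with ``monomorphic=True``.
    """
    if df_mode not in DF_MODES:
        raise ValueError(f"df_mode must be one of {DF_MODES}, got {df_mode!r}")
    n = counts.n_total
    if n == 0:
        raise EmptyLocusError(f"locus {counts.locus.id!r}: no genotyped samples")
    spectrum = allele_frequencies(counts)
    p = spectrum.frequency(counts.locus.allele_ref)
    q = 1.0 - p
    expected = (n * p * p, n * 2.0 * p * q, n * q * q)
    df = 2 if df_mode == "paper" else 1
    if p == 0.0 or q == 0.0:
        return HWETestResult(counts.locus, expected, 0.0, df, 1.0, monomorphic=True)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts.counts, expected))
    p_value = float(stats.chi2.sf(chi2, df))
    return HWETestResult(counts.locus, expected, chi2, df, p_value)
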