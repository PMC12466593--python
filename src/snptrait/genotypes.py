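"""Data model for biallelic SNP loci, samples and genotype tabulation.

A :class:`Locus` declares a reference and alternative allele; a
:class:`SampleRecord` carries one unordered genotype call per locus plus sex
and quantitative traits. Calls are canonicalized so that "CA" and "AC" name
the same heterozygote class. Tabulation produces a
:class:`GenotypeCountTable` (the three genotype-class counts of a biallelic
marker) and an :class:`AlleleFrequencySpectrum`, the basis of every
downstream diversity statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import EmptyLocusError, ValidationError

#: Sentinel for an absent genotype call.
MISSING = None

SEXES = ("F", "M")

#: Canonical order of the three genotype classes of a biallelic locus.
GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP with declared reference and alternative alleles.

    Parameters
    ----------
    id
        Unique label, e.g. ``"g.57337C>A"``. Coordinates in the label are
        treated as opaque text.
    allele_ref, allele_alt
        Single-character allele symbols; must differ.
    region_label
        Optional free-text location such as ``"exon 5"``.
    """

    id: str
    allele_ref: str
    allele_alt: str
    region_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("locus id must be non-empty")
        for a in (self.allele_ref, self.allele_alt):
            if len(a) != 1:
                raise ValidationError(
                    f"locus {self.id!r}: allele symbol {a!r} must be a single character"
                )
        if self.allele_ref == self.allele_alt:
            raise ValidationError(f"locus {self.id!r}: ref and alt alleles are identical")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_ref, self.allele_alt)

    def genotype_label(self, klass: str) -> str:
        """Two-letter display label for a genotype class, e.g. ``"CA"``."""
        if klass == "hom_ref":
            return self.allele_ref * 2
        if klass == "het":
            return self.allele_ref + self.allele_alt
        if klass == "hom_alt":
            return self.allele_alt * 2
        raise ValueError(f"unknown genotype class {klass!r}")


def canonical_call(call: str | tuple[str, str] | None) -> Optional[tuple[str, str]]:
    """Normalize a genotype call to a sorted allele tuple.

    Accepts a two-character string ("CA"), a pair of symbols, or
    ``None``/empty for missing. Orientation is discarded: "CA" and "AC"
    canonicalize identically.
    """
    if call is None:
        return MISSING
    if isinstance(call, str):
        s = call.strip()
        if not s:
            return MISSING
        if len(s) != 2:
            raise ValidationError(f"genotype call {call!r} is not two allele symbols")
        pair = (s[0], s[1])
    else:
        pair = tuple(call)  # type: ignore[assignment]
        if len(pair) != 2:
            raise ValidationError(f"genotype call {call!r} is not an allele pair")
    return tuple(sorted(pair))  # type: ignore[return-value]


@dataclass
class SampleRecord:
    """One individual: id, sex, genotype calls and trait values (grams)."""

    sample_id: str
    sex: str
    calls: dict[str, Optional[tuple[str, str]]] = field(default_factory=dict)
    traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(
                f"sample {self.sample_id!r}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        self.calls = {k: canonical_call(v) for k, v in self.calls.items()}
        for name, value in self.traits.items():
            v = float(value)
            if not (v >= 0.0) or v != v:
                raise ValidationError(
                    f"sample {self.sample_id!r}: trait {name!r} must be finite and >= 0"
                )

    def genotype_class(self, locus: Locus) -> Optional[str]:
        """Classify this sample's call at ``locus`` into hom_ref/het/hom_alt.

        Raises :class:`ValidationError` if the call uses an undeclared allele.
        """
        call = self.calls.get(locus.id, MISSING)
        if call is MISSING:
            return None
        a, b = call
        declared = set(locus.alleles)
        if not {a, b} <= declared:
            raise ValidationError(
                f"sample {self.sample_id!r}, locus {locus.id!r}: call {a}{b} uses an "
                f"allele not in declared set {sorted(declared)}"
            )
        if a == b:
            return "hom_ref" if a == locus.allele_ref else "hom_alt"
        return "het"


@dataclass(frozen=True)
class GenotypeCountTable:
    """Counts of the three genotype classes at one biallelic locus."""

    locus: Locus
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for n in (self.n_hom_ref, self.n_het, self.n_hom_alt):
            if n < 0:
                raise ValidationError(f"locus {self.locus.id!r}: negative genotype count")

    @property
    def n_total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_hom_ref, self.n_het, self.n_hom_alt)


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Allele -> relative frequency map at one locus.

    Frequencies are allele-count ratios computed at full double precision:
    freq(ref) = (2*hom_ref + het) / (2*n_total). No rounding happens here;
    display rounding is a report-layer concern.
    """

    locus: Locus
    freqs: Mapping[str, float]
    n_alleles_observed: int
    allele_count_denominator: int

    def frequency(self, allele: str) -> float:
        return self.freqs[allele]

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(self.freqs.values())


def count_genotypes(records: Iterable[SampleRecord], locus: Locus) -> GenotypeCountTable:
    """Tabulate non-missing genotype calls at ``locus`` into class counts.

    Missing calls are dropped (complete-case per locus); heterozygote
    orientation has already been collapsed by call canonicalization.
    """
    tally = {"hom_ref": 0, "het": 0, "hom_alt": 0}
    for rec in records:
        klass = rec.genotype_class(locus)
        if klass is not None:
            tally[klass] += 1
    return GenotypeCountTable(locus, tally["hom_ref"], tally["het"], tally["hom_alt"])


def allele_frequencies(counts: GenotypeCountTable) -> AlleleFrequencySpectrum:
    """Allele frequencies by direct allele counting from genotype counts."""
    n = counts.n_total
    if n == 0:
        raise EmptyLocusError(f"locus {counts.locus.id!r}: no genotyped samples")
    denom = 2 * n
    n_ref = 2 * counts.n_hom_ref + counts.n_het
    freq_ref = n_ref / denom
    freqs = {counts.locus.allele_ref: freq_ref, counts.locus.allele_alt: 1.0 - freq_ref}
    n_observed = sum(1 for f in freqs.values() if f > 0.0)
    return AlleleFrequencySpectrum(
        locus=counts.locus,
        freqs=freqs,
        n_alleles_observed=n_observed,
        allele_count_denominator=denom,
    )


def genotype_frequencies(counts: GenotypeCountTable) -> dict[str, float]:
    """Relative frequency of each genotype class (full precision)."""
    n = counts.n_total
    if n == 0:
        raise EmptyLocusError(f"locus {counts.locus.id!r}: no genotyped samples")
    return {
        "hom_ref": counts.n_hom_ref / n,
        "het": counts.n_het / n,
        "hom_alt": counts.n_hom_alt / n,
    }
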