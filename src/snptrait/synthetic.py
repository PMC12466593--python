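"""Synthetic cohorts with the statistical structure the analysis assumes.

The study population this package targets — a pedigreed meat-chicken line
genotyped at a handful of candidate-gene SNPs, weighed through growth and at
slaughter — is rarely deposited publicly, so every pipeline stage is
exercised against simulated cohorts with known ground truth instead.

Three generators are provided, all driven by a single integer seed through
``numpy.random.default_rng`` so regeneration is bit-identical:

* genotypes: each bird's genotype class at a locus is drawn from the
  inbreeding-parameterized Hardy-Weinberg classes
  (p^2 + Fpq, 2pq(1-F), q^2 + Fpq); F > 0 produces the heterozygote
  deficit that a departure from random mating leaves in real data.
* traits: Y = mu + g[genotype] + s[sex] + N(0, sigma^2), the sampling
  counterpart of the fixed-effects model the association module fits.
* qPCR plates: reference-gene Ct ~ N(mu_ref, sigma_ct^2) and target-gene
  Ct = mu_target - log2(fold[group]) + noise, so the recovered fold change
  is unbiased on the log2 scale.

``paper_preset`` builds a cohort of the default shape: 176 birds (133
female, 43 male), four biallelic loci at the allele frequencies such a
candidate-gene panel shows (two moderately polymorphic loci with
heterozygote deficit, two low-polymorphism loci near equilibrium), and
growth/carcass traits on gram scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotypes import GENOTYPE_CLASSES, Locus, SampleRecord


@dataclass(frozen=True)
class LocusSimSpec:
    """One locus to simulate: ref-allele frequency p and inbreeding F."""

    locus: Locus
    p_ref: float
    inbreeding_f: float = 0.0

    def class_probabilities(self) -> tuple[float, float, float]:
        """(hom_ref, het, hom_alt) probabilities under the F-model."""
        p, f = self.p_ref, self.inbreeding_f
        if not 0.0 < p < 1.0:
            raise ValidationError(f"p_ref must be in (0,1), got {p}")
        q = 1.0 - p
        probs = (p * p + f * p * q, 2.0 * p * q * (1.0 - f), q * q + f * p * q)
        if any(pr < -1e-12 or pr > 1.0 + 1e-12 for pr in probs):
            raise ValidationError(
                f"locus {self.locus.id!r}: class probabilities {probs} invalid "
                f"for p={p}, F={f}"
            )
        return tuple(max(0.0, min(1.0, pr)) for pr in probs)  # type: ignore[return-value]


@dataclass(frozen=True)
class TraitSimSpec:
    """Additive trait model: mu + genotype effect + sex effect + noise (grams)."""

    name: str
    mu: float
    genotype_effects: tuple[float, float, float]   # hom_ref, het, hom_alt
    sex_effect: float                              # added for males; females reference
    sigma: float
    locus_id: Optional[str] = None                 # defaults to the first locus

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError(f"trait {self.name!r}: sigma must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to regenerate a cohort deterministically."""

    n_female: int
    n_male: int
    loci: tuple[LocusSimSpec, ...]
    traits: tuple[TraitSimSpec, ...]
    seed: int

    @property
    def n_samples(self) -> int:
        return self.n_female + self.n_male


@dataclass(frozen=True)
class SimulatedCohort:
    """Generated records plus the spec that is their ground truth."""

    records: tuple[SampleRecord, ...]
    truth: CohortSpec


def simulate_genotypes(
    spec: LocusSimSpec, n: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Draw n genotype calls at one locus; counts are multinomial."""
    probs = spec.class_probabilities()
    classes = rng.choice(3, size=n, p=probs)
    locus = spec.locus
    pairs = [
        tuple(sorted((locus.allele_ref, locus.allele_ref))),
        tuple(sorted((locus.allele_ref, locus.allele_alt))),
        tuple(sorted((locus.allele_alt, locus.allele_alt))),
    ]
    return [pairs[c] for c in classes]


def simulate_traits(
    genotype_classes: Sequence[str],
    sexes: Sequence[str],
    spec: TraitSimSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Trait values under Y = mu + g[genotype] + s[sex] + N(0, sigma^2)."""
    if len(genotype_classes) != len(sexes):
        raise ValidationError("genotype and sex vectors differ in length")
    g = dict(zip(GENOTYPE_CLASSES, spec.genotype_effects))
    mean = np.array(
        [
            spec.mu + g[klass] + (spec.sex_effect if sex == "M" else 0.0)
            for klass, sex in zip(genotype_classes, sexes)
        ]
    )
    noise = rng.normal(0.0, spec.sigma, size=len(mean)) if spec.sigma > 0 else 0.0
    return mean + noise


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a full cohort (genotypes + traits) from a spec, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sexes = ["F"] * spec.n_female + ["M"] * spec.n_male
    calls_by_locus = {
        ls.locus.id: simulate_genotypes(ls, n, rng) for ls in spec.loci
    }
    classes_by_locus = {}
    for ls in spec.loci:
        locus = ls.locus
        ref_pair = tuple(sorted((locus.allele_ref, locus.allele_ref)))
        het_pair = tuple(sorted((locus.allele_ref, locus.allele_alt)))
        classes_by_locus[locus.id] = [
            "hom_ref" if c == ref_pair else ("het" if c == het_pair else "hom_alt")
            for c in calls_by_locus[locus.id]
        ]
    default_locus = spec.loci[0].locus.id if spec.loci else None
    traits_by_name = {}
    for ts in spec.traits:
        locus_id = ts.locus_id or default_locus
        if locus_id is None:
            raise ValidationError(f"trait {ts.name!r}: no locus to attach effects to")
        traits_by_name[ts.name] = simulate_traits(
            classes_by_locus[locus_id], sexes, ts, rng
        )
    width = len(str(n))
    records = tuple(
        SampleRecord(
            sample_id=f"S{i + 1:0{width}d}",
            sex=sexes[i],
            calls={lid: calls[i] for lid, calls in calls_by_locus.items()},
            traits={name: float(vals[i]) for name, vals in traits_by_name.items()},
        )
        for i in range(n)
    )
    return SimulatedCohort(records=records, truth=spec)


def simulate_ct(
    fold_by_group: Mapping[str, float],
    n_per_group: int,
    sigma_ct: float,
    seed: int,
    mu_reference: float = 20.0,
    mu_target: float = 25.0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """qPCR Ct table for a target and reference gene across groups.

    Each group's true fold change (relative to a fold-1 group) shifts the
    target-gene Ct by -log2(fold); Gaussian noise of SD ``sigma_ct`` cycles
    is added per well. Returns the long-format frame
    ``sample_id, group, gene_role, replicate, ct``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in fold_by_group.items():
        if fold <= 0:
            raise ValidationError(f"group {group!r}: fold change must be > 0")
        for i in range(n_per_group):
            sid = f"{group}_s{i + 1}"
            for rep in range(1, n_replicates + 1):
                ref_ct = mu_reference + rng.normal(0.0, sigma_ct)
                tgt_ct = mu_target - np.log2(fold) + rng.normal(0.0, sigma_ct)
                rows.append((sid, group, "reference", rep, ref_ct))
                rows.append((sid, group, "target", rep, tgt_ct))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene_role", "replicate", "ct"]
    )


def paper_preset(seed: int = 0) -> CohortSpec:
    """Default cohort: 176 birds (133 F / 43 M), four SNPs, gram-scale traits.

    The two moderately polymorphic loci carry positive inbreeding
    coefficients sized to their observed heterozygote deficits; the two
    low-polymorphism loci sit at equilibrium. Trait scales and qualitative
    genotype-effect patterns follow a 16-week meat-chicken cohort.
    """
    loci = (
        LocusSimSpec(
            Locus("g.57337C>A", "C", "A", "exon 5"), p_ref=0.764, inbreeding_f=0.26
        ),
        LocusSimSpec(
            Locus("g.64757T>G", "T", "G", "exon 7"), p_ref=0.261, inbreeding_f=0.28
        ),
        LocusSimSpec(
            Locus("g.97213G>A", "G", "A", "exon 8"), p_ref=0.952, inbreeding_f=0.0
        ),
        LocusSimSpec(
            Locus("g.220985G>A", "G", "A", "exon 9"), p_ref=0.949, inbreeding_f=0.0
        ),
    )
    traits = (
        # hom-ref (CC) lowest; het and hom-alt close, as the slaughter-weight
        # letter patterns of such cohorts show
        TraitSimSpec("live_weight_16w", 1360.0, (0.0, 80.0, 95.0), 180.0, 230.0),
        TraitSimSpec("slaughter_weight", 1180.0, (0.0, 60.0, 80.0), 160.0, 220.0),
        TraitSimSpec("breast_muscle_weight", 62.0, (0.0, 8.0, 8.0), 10.0, 12.0),
        TraitSimSpec("heart_weight", 5.9, (0.0, 1.1, 1.0), 0.8, 2.1),
        TraitSimSpec("body_weight_8w", 620.0, (0.0, 60.0, 40.0), 70.0, 100.0),
    )
    return CohortSpec(n_female=133, n_male=43, loci=loci, traits=traits, seed=seed)
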