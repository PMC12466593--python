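"""Report rendering and run configuration.

Two output layers: a full-precision machine-readable layer (dicts meant for
JSON) and a rounded display layer (TSV-shaped DataFrames) that mirrors how
marker-diversity and trait-association tables are conventionally printed.
All rounding is half-away-from-zero and happens only here.

The HWE chi-square is displayed to 2 decimals and its p-value to 3, both
rounded from the full-precision values; the JSON layer carries them exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .association import GenotypeTraitSummary
from .diversity import diversity_stats, hwe_test
from .errors import ValidationError
from .genotypes import (
    GENOTYPE_CLASSES,
    Locus,
    SampleRecord,
    allele_frequencies,
    count_genotypes,
    genotype_frequencies,
)
from .rounding import round_half_up


@dataclass(frozen=True)
class RunConfig:
    """Shared analysis settings with table-convention defaults."""

    alpha: float = 0.05
    alpha_high: float = 0.01
    hwe_df_mode: str = "paper"
    mc_method: str = "lsd"
    seed: int = 0
    round_freq: int = 3
    round_stat: int = 3      # H, PIC, Ne, p
    round_chi2: int = 2
    round_mean: int = 2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.alpha_high < self.alpha:
            raise ValidationError(
                f"alpha_high ({self.alpha_high}) must be below alpha ({self.alpha})"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def diversity_results(
    records: Sequence[SampleRecord],
    loci: Sequence[Locus],
    df_mode: str = "paper",
) -> list[dict]:
    """Full-precision per-locus diversity + HWE results (JSON-ready)."""
    out = []
    for locus in loci:
        counts = count_genotypes(records, locus)
        spectrum = allele_frequencies(counts)
        stats = diversity_stats(spectrum)
        hwe = hwe_test(counts, df_mode=df_mode)
        out.append(
            {
                "locus": locus.id,
                "region": locus.region_label,
                "counts": {
                    locus.genotype_label(k): c
                    for k, c in zip(GENOTYPE_CLASSES, counts.counts)
                },
                "n_total": counts.n_total,
                "genotype_freqs": {
                    locus.genotype_label(k): v
                    for k, v in genotype_frequencies(counts).items()
                },
                "allele_freqs": dict(spectrum.freqs),
                "H": stats.H,
                "PIC": stats.PIC,
                "Ne": stats.Ne,
                "polymorphism_class": stats.polymorphism_class,
                "chi2": hwe.chi2,
                "df": hwe.df,
                "p_value": hwe.p_value,
                "expected_counts": list(hwe.expected_counts),
                "monomorphic": hwe.monomorphic,
            }
        )
    return out


def render_diversity_table(
    results: Iterable[dict], config: RunConfig = RunConfig(), rounded: bool = True
) -> pd.DataFrame:
    """Display table with one row per genotype class, stats on the first row.

    Columns mirror the conventional marker-polymorphism table: locus,
    genotype, N, genotypic frequency, allele, allelic frequency, chi2, p,
    H, PIC, Ne, polymorphism class.
    """
    rows = []
    for res in results:
        genotype_items = list(res["counts"].items())
        allele_items = list(res["allele_freqs"].items())
        if rounded:
            chi2_disp = round_half_up(res["chi2"], config.round_chi2)
            p_disp = round_half_up(res["p_value"], config.round_stat)
        else:
            chi2_disp, p_disp = res["chi2"], res["p_value"]

        def _r(x, nd):
            return round_half_up(x, nd) if rounded else x

        for i, (glabel, n) in enumerate(genotype_items):
            allele, afreq = allele_items[i] if i < len(allele_items) else ("", None)
            first = i == 0
            rows.append(
                {
                    "locus": res["locus"] if first else "",
                    "genotype": glabel,
                    "N": n,
                    "genotypic_freq": _r(
                        res["genotype_freqs"][glabel], config.round_freq
                    ),
                    "allele": allele,
                    "allelic_freq": _r(afreq, config.round_freq) if afreq is not None else "",
                    "chi2": chi2_disp if first else "",
                    "p": p_disp if first else "",
                    "H": _r(res["H"], config.round_stat) if first else "",
                    "PIC": _r(res["PIC"], config.round_stat) if first else "",
                    "Ne": _r(res["Ne"], config.round_stat) if first else "",
                    "polymorphism_class": res["polymorphism_class"] if first else "",
                }
            )
    return pd.DataFrame(rows)


def render_association_table(
    summaries: Sequence[GenotypeTraitSummary], config: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Display table: one row per trait x genotype with means, SDs, letters."""
    rows = []
    for s in summaries:
        for level in s.genotype_levels:
            rows.append(
                {
                    "trait": s.trait_name,
                    "locus": s.locus.id,
                    "genotype": s.locus.genotype_label(level),
                    "n": s.ns[level],
                    "mean": round_half_up(s.means[level], config.round_mean),
                    "sd": round_half_up(s.sds[level], config.round_mean),
                    "letters_005": s.letters_low[level],
                    "letters_001": s.letters_high[level],
                    "cell": s.cell(level, config.round_mean),
                    "genotype_F": round_half_up(s.genotype_F, config.round_stat),
                    "genotype_p": round_half_up(s.genotype_p, config.round_stat),
                }
            )
    return pd.DataFrame(rows)


def association_results(summaries: Sequence[GenotypeTraitSummary]) -> list[dict]:
    """Full-precision association summaries (JSON-ready)."""
    out = []
    for s in summaries:
        out.append(
            {
                "trait": s.trait_name,
                "locus": s.locus.id,
                "genotype_F": s.genotype_F,
                "genotype_p": s.genotype_p,
                "groups": {
                    s.locus.genotype_label(level): {
                        "n": s.ns[level],
                        "mean": s.means[level],
                        "sd": s.sds[level],
                        "letters_005": s.letters_low[level],
                        "letters_001": s.letters_high[level],
                    }
                    for level in s.genotype_levels
                },
            }
        )
    return out


def render_expression_table(results, comparisons, config: RunConfig = RunConfig()):
    """Per-sample fold-change table and group-comparison table (rounded)."""
    folds = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "group": [r.group for r in results],
            "delta_ct": [round_half_up(r.delta_ct, config.round_stat) for r in results],
            "delta_delta_ct": [
                round_half_up(r.delta_delta_ct, config.round_stat) for r in results
            ],
            "fold_change": [
                round_half_up(r.fold_change, config.round_stat) for r in results
            ],
        }
    )
    comps = pd.DataFrame(
        {
            "group_a": [c.group_a for c in comparisons],
            "group_b": [c.group_b for c in comparisons],
            "t": [round_half_up(c.t, config.round_stat) for c in comparisons],
            "df": [c.df for c in comparisons],
            "p": [round_half_up(c.p, config.round_stat) for c in comparisons],
            "mark": [c.significance_mark for c in comparisons],
        }
    )
    return folds, comps
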