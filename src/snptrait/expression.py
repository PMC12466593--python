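"""Relative gene expression by the 2^-ddCt (Livak) method.

Each sample contributes a target-gene and a reference-gene Ct value
(technical replicates are averaged on the Ct scale first). Then

    dCt_i   = Ct_target,i - Ct_reference,i
    ddCt_i  = dCt_i - mean(dCt over the calibrator group)
    fold_i  = 2 ** (-ddCt_i)

so the calibrator group has geometric-mean fold change 1 by construction.
Group differences are tested with a two-sided Student's t-test, by default
on the dCt scale (approximately normal; fold changes are log-normal), with
Welch's unequal-variance variant available. Amplification efficiency is
assumed to be 2 per cycle for both genes (no efficiency correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, ValidationError

GENE_ROLES = ("target", "reference")
TEST_SCALES = ("dct", "fold")


@dataclass(frozen=True)
class CtMeasurement:
    """One well: sample, group label, gene role (target/reference), Ct."""

    sample_id: str
    group: str
    gene_role: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.gene_role not in GENE_ROLES:
            raise ValidationError(
                f"sample {self.sample_id!r}: gene_role must be one of {GENE_ROLES}, "
                f"got {self.gene_role!r}"
            )
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValidationError(
                f"sample {self.sample_id!r}: Ct must be a positive finite cycle "
                f"number, got {self.ct!r}"
            )


@dataclass(frozen=True)
class RelativeExpression:
    """Per-sample dCt, ddCt and fold change relative to the calibrator mean."""

    sample_id: str
    group: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-group t-test with the figure-legend significance mark."""

    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    significance_mark: str   # "ns", "*", "**"


def significance_mark(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def delta_ct(measurements: Iterable[CtMeasurement]) -> float:
    """dCt for one sample: mean target Ct minus mean reference Ct.

    Technical replicates of a role are averaged arithmetically on the Ct
    scale before subtraction.
    """
    by_role: dict[str, list[float]] = {"target": [], "reference": []}
    sample = None
    for m in measurements:
        sample = m.sample_id
        by_role[m.gene_role].append(m.ct)
    for role, cts in by_role.items():
        if not cts:
            raise PairingError(
                f"sample {sample!r}: no {role} Ct measurement; cannot form dCt"
            )
    return float(np.mean(by_role["target"]) - np.mean(by_role["reference"]))


def relative_expression(
    measurements: Iterable[CtMeasurement], calibrator_group: str
) -> list[RelativeExpression]:
    """Per-sample fold changes relative to the calibrator group's mean dCt."""
    by_sample: dict[tuple[str, str], list[CtMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault((m.sample_id, m.group), []).append(m)
    dcts = {key: delta_ct(ms) for key, ms in by_sample.items()}
    calib = [v for (sid, grp), v in dcts.items() if grp == calibrator_group]
    if not calib:
        raise ValidationError(
            f"calibrator group {calibrator_group!r} has no samples"
        )
    calib_mean = float(np.mean(calib))
    out = []
    for (sid, grp), d in dcts.items():
        dd = d - calib_mean
        out.append(
            RelativeExpression(
                sample_id=sid, group=grp, delta_ct=d,
                delta_delta_ct=dd, fold_change=2.0 ** (-dd),
            )
        )
    return out


def students_t_test(
    group_a: Sequence[RelativeExpression],
    group_b: Sequence[RelativeExpression],
    scale: str = "dct",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided t-test between two groups of relative-expression results.

    ``scale="dct"`` (default) compares dCt values; ``scale="fold"`` compares
    fold changes directly. Student's pooled-variance test unless ``welch``.
    """
    if scale not in TEST_SCALES:
        raise ValidationError(f"unknown test scale {scale!r}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples for a t-test")
    attr = "delta_ct" if scale == "dct" else "fold_change"
    xa = np.array([getattr(r, attr) for r in group_a])
    xb = np.array([getattr(r, attr) for r in group_b])
    res = stats.ttest_ind(xa, xb, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(xa) + len(xb) - 2)
    p = float(res.pvalue)
    return GroupComparison(
        group_a=group_a[0].group, group_b=group_b[0].group,
        t=float(res.statistic), df=df, p=p,
        significance_mark=significance_mark(p),
    )


def compare_groups(
    results: Sequence[RelativeExpression],
    pairs: Sequence[tuple[str, str]] | None = None,
    scale: str = "dct",
    welch: bool = False,
) -> list[GroupComparison]:
    """t-tests for the requested (or all adjacent) group pairs."""
    by_group: dict[str, list[RelativeExpression]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)
    groups = list(by_group)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    out = []
    for a, b in pairs:
        if a not in by_group or b not in by_group:
            raise ValidationError(f"unknown group in pair ({a!r}, {b!r})")
        out.append(students_t_test(by_group[a], by_group[b], scale=scale, welch=welch))
    return out


def results_frame(results: Sequence[RelativeExpression]) -> pd.DataFrame:
    """Tabular view of per-sample relative-expression results."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "group": [r.group for r in results],
            "delta_ct": [r.delta_ct for r in results],
            "delta_delta_ct": [r.delta_delta_ct for r in results],
            "fold_change": [r.fold_change for r in results],
        }
    )
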