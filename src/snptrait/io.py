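"""Reading and validating genotype, trait and qPCR Ct tables; VCF import.

Formats
-------
Genotype CSV
    Header ``sample_id,sex,<locus1>,<locus2>,...``; sex is F or M; genotype
    cells hold two allele characters in either orientation ("CA" == "AC")
    or are empty for a missing call.
Trait CSV
    ``sample_id`` plus one numeric column per trait (grams).
Expression CSV
    ``sample_id,group,gene_role,replicate,ct`` with gene_role in
    {target, reference}.
VCF
    Biallelic SNP records only; GT 0/0, 0/1 (or 1/0), 1/1 and ./. map to
    hom-ref, het, hom-alt and missing. Sample sex comes from a sidecar CSV
    (``sample_id,sex``) because VCF carries none.

Validation errors name the offending row and file so they can be fixed at
the source.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .errors import ValidationError
from .genotypes import Locus, SampleRecord, canonical_call


def read_locus_manifest(path: str | Path) -> list[Locus]:
    """Load locus declarations from YAML: list of {id, ref, alt, region}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValidationError(f"{path}: locus manifest must be a YAML list")
    loci = []
    for entry in raw:
        try:
            loci.append(
                Locus(
                    id=entry["id"],
                    allele_ref=entry["ref"],
                    allele_alt=entry["alt"],
                    region_label=entry.get("region"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"{path}: malformed manifest entry {entry!r}") from exc
    return loci


def write_locus_manifest(loci: Sequence[Locus], path: str | Path) -> None:
    entries = [
        {"id": lc.id, "ref": lc.allele_ref, "alt": lc.allele_alt, "region": lc.region_label}
        for lc in loci
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def _infer_loci(header: list[str], rows: list[dict[str, str]]) -> list[Locus]:
    """Infer each column's two alleles; the more frequent symbol becomes ref."""
    loci = []
    for col in header:
        tally: dict[str, int] = {}
        for row in rows:
            call = canonical_call(row[col])
            if call is None:
                continue
            for a in call:
                tally[a] = tally.get(a, 0) + 1
        symbols = sorted(tally, key=lambda a: (-tally[a], a))
        if len(symbols) != 2:
            raise ValidationError(
                f"locus column {col!r}: found {len(symbols)} allele symbol(s) "
                f"{symbols}; declare a locus manifest to disambiguate"
            )
        loci.append(Locus(id=col, allele_ref=symbols[0], allele_alt=symbols[1]))
    return loci


def read_genotype_table(
    path: str | Path, loci: Optional[Sequence[Locus]] = None
) -> tuple[list[SampleRecord], list[Locus]]:
    """Read a genotype CSV into validated sample records.

    When ``loci`` is given, each column is checked against the declared
    allele set; otherwise per-locus allele sets are inferred from the data
    (major symbol = ref). Returns the records together with the locus list
    in column order.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[:2] != ["sample_id", "sex"]:
            raise ValidationError(
                f"{path}: header must start with 'sample_id,sex', got {reader.fieldnames}"
            )
        locus_cols = list(reader.fieldnames[2:])
        rows = list(reader)

    if loci is None:
        loci_list = _infer_loci(locus_cols, rows)
    else:
        by_id = {lc.id: lc for lc in loci}
        missing = [c for c in locus_cols if c not in by_id]
        if missing:
            raise ValidationError(f"{path}: columns {missing} absent from locus manifest")
        loci_list = [by_id[c] for c in locus_cols]

    records: list[SampleRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):  # data starts on file line 2
        sid = (row.get("sample_id") or "").strip()
        if not sid:
            raise ValidationError(f"{path} line {i}: empty sample_id")
        if sid in seen:
            raise ValidationError(f"{path} line {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        sex = (row.get("sex") or "").strip()
        if sex not in ("F", "M"):
            raise ValidationError(
                f"{path} line {i}: sex must be F or M, got {sex!r}"
            )
        calls = {}
        for lc in loci_list:
            try:
                calls[lc.id] = canonical_call(row[lc.id])
            except ValidationError as exc:
                raise ValidationError(f"{path} line {i}: {exc}") from exc
        rec = SampleRecord(sample_id=sid, sex=sex, calls=calls)
        # validate alleles against declarations up front so errors carry rows
        for lc in loci_list:
            try:
                rec.genotype_class(lc)
            except ValidationError as exc:
                raise ValidationError(f"{path} line {i}: {exc}") from exc
        records.append(rec)
    return records, loci_list


def write_genotype_table(
    records: Iterable[SampleRecord], loci: Sequence[Locus], path: str | Path
) -> None:
    """Write records to genotype CSV (canonical call orientation)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "sex", *(lc.id for lc in loci)])
        for rec in records:
            cells = []
            for lc in loci:
                call = rec.calls.get(lc.id)
                cells.append("" if call is None else "".join(call))
            writer.writerow([rec.sample_id, rec.sex, *cells])


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a trait CSV (sample_id + numeric gram-scale columns)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: trait table needs a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    for col in df.columns.drop("sample_id"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            row = int(vals.index[vals < 0][0]) + 2
            raise ValidationError(f"{path} line {row}: trait {col!r} is negative")
        df[col] = vals
    return df


def write_trait_table(
    records: Iterable[SampleRecord], trait_names: Sequence[str], path: str | Path
) -> None:
    rows = []
    for rec in records:
        rows.append(
            {"sample_id": rec.sample_id, **{t: rec.traits.get(t) for t in trait_names}}
        )
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def attach_traits(records: Sequence[SampleRecord], traits: pd.DataFrame) -> None:
    """Join trait columns onto sample records in place (by sample_id)."""
    by_id = traits.set_index("sample_id")
    trait_cols = list(by_id.columns)
    for rec in records:
        if rec.sample_id in by_id.index:
            row = by_id.loc[rec.sample_id]
            for col in trait_cols:
                val = row[col]
                if pd.notna(val):
                    rec.traits[col] = float(val)


def read_expression_table(path: str | Path):
    """Read an expression CSV into CtMeasurement objects."""
    from .expression import CtMeasurement

    df = pd.read_csv(path)
    required = {"sample_id", "group", "gene_role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: expression table lacks columns {sorted(missing)}")
    measurements = []
    for i, row in df.iterrows():
        try:
            measurements.append(
                CtMeasurement(
                    sample_id=str(row["sample_id"]),
                    group=str(row["group"]),
                    gene_role=str(row["gene_role"]),
                    ct=float(row["ct"]),
                    replicate=int(row.get("replicate", 1)) if "replicate" in df.columns else 1,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {int(i) + 2}: {exc}") from exc
    return measurements


def _read_sex_sidecar(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"sample_id", "sex"} <= set(df.columns):
        raise ValidationError(f"{path}: sex sidecar needs columns sample_id,sex")
    out = {}
    for i, row in df.iterrows():
        sex = str(row["sex"]).strip()
        if sex not in ("F", "M"):
            raise ValidationError(f"{path} line {int(i) + 2}: sex must be F or M, got {sex!r}")
        out[str(row["sample_id"])] = sex
    return out


def import_vcf(
    path: str | Path, sex_sidecar: str | Path
) -> tuple[list[SampleRecord], list[Locus]]:
    """Import biallelic SNP genotypes from a VCF.

    Multi-allelic or non-SNP records are rejected with an explicit error.
    Locus ids come from the ID field when set, else ``CHROM:POSREF>ALT``.
    """
    from cyvcf2 import VCF

    sex_by_id = _read_sex_sidecar(sex_sidecar)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in sex_by_id]
    if missing:
        raise ValidationError(
            f"{path}: samples {missing} absent from sex sidecar {sex_sidecar}"
        )
    loci: list[Locus] = []
    calls_per_sample: dict[str, dict[str, Optional[tuple[str, str]]]] = {
        s: {} for s in samples
    }
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValidationError(
                f"{path}: record {variant.CHROM}:{variant.POS} is multi-allelic "
                f"(ALT={variant.ALT}); split or filter it first"
            )
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            raise ValidationError(
                f"{path}: record {variant.CHROM}:{variant.POS} is not a SNP "
                f"({ref}>{alt})"
            )
        locus_id = variant.ID or f"{variant.CHROM}:{variant.POS}{ref}>{alt}"
        locus = Locus(id=locus_id, allele_ref=ref, allele_alt=alt)
        loci.append(locus)
        alleles = (ref, alt)
        for sample, gt in zip(samples, variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                calls_per_sample[sample][locus_id] = None
            else:
                calls_per_sample[sample][locus_id] = tuple(
                    sorted((alleles[a], alleles[b]))
                )
    records = [
        SampleRecord(sample_id=s, sex=sex_by_id[s], calls=calls_per_sample[s])
        for s in samples
    ]
    return records, loci
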