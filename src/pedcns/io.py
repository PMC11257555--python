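"""Readers and writers for the tabular formats the pipeline touches.

MAF files are tab-delimited with ``#`` comment lines and 1-based inclusive
coordinates; SEG and BED inputs are converted to the 0-based half-open
convention on the way in. All writers emit plain TSV.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .errors import FormatError, RowError
from .intervals import GenomicInterval, IntervalSet
from .model import (
    ConsensusVariant,
    CnvSegment,
    FusionCall,
    MethylPrediction,
    SpecimenRecord,
    VariantRecord,
    normalize_chrom,
    status_from_copy_number,
)

MAF_REQUIRED = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
    "t_depth",
    "t_alt_count",
    "n_depth",
]

MAF_OPTIONAL = ["HGVSp_Short", "gnomAD_AF", "HotSpotAllele", "callers", "consensus_reason"]

_TRUTHY = {"yes", "true", "1", "y"}


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kwargs)


def _opt_int(value: str, row: int, column: str) -> Optional[int]:
    if value in ("", "NA", ".", "nan", "None"):
        return None
    try:
        return int(float(value))
    except ValueError:
        raise RowError(f"unparseable {column}: {value!r}", row=row)


def _opt_float(value: str) -> Optional[float]:
    if value in ("", "NA", ".", "nan", "None"):
        return None
    return float(value)


def read_maf(path, caller: str = "", hotspot_column: str = "HotSpotAllele") -> List[VariantRecord]:
    """Read a MAF-dialect TSV into :class:`VariantRecord` objects.

    ``caller`` seeds the provenance set of every record; when the file
    already carries a ``callers`` column (consensus output) that column
    wins. Coordinates stay 1-based inclusive.
    """
    df = _read_tsv(path)
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"MAF file {path} is missing mandatory column {col!r}")
    records: List[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        if "callers" in df.columns and row["callers"]:
            callers = frozenset(row["callers"].split(","))
        elif caller:
            callers = frozenset({caller})
        else:
            callers = frozenset()
        hotspot = row.get(hotspot_column, "").strip().lower() in _TRUTHY
        records.append(
            VariantRecord(
                sample_id=row["Tumor_Sample_Barcode"],
                chrom=normalize_chrom(row["Chromosome"]),
                start=int(row["Start_Position"]),
                end=int(row["End_Position"]),
                ref=row["Reference_Allele"],
                alt=row["Tumor_Seq_Allele2"],
                variant_class=row["Variant_Classification"],
                variant_type=row["Variant_Type"],
                gene=row["Hugo_Symbol"],
                protein_change=row.get("HGVSp_Short", ""),
                callers=callers,
                t_depth=_opt_int(row["t_depth"], i, "t_depth"),
                alt_depth=_opt_int(row["t_alt_count"], i, "t_alt_count"),
                n_depth=_opt_int(row["n_depth"], i, "n_depth"),
                gnomad_af=_opt_float(row.get("gnomAD_AF", "")),
                hotspot=hotspot,
            )
        )
    return records


def variants_to_frame(records: Sequence[VariantRecord], reasons: Optional[Dict] = None) -> pd.DataFrame:
    """MAF-dialect DataFrame for a collection of variant records."""
    rows = []
    for rec in records:
        rows.append(
            {
                "Hugo_Symbol": rec.gene,
                "Chromosome": rec.chrom,
                "Start_Position": rec.start,
                "End_Position": rec.end,
                "Reference_Allele": rec.ref,
                "Tumor_Seq_Allele2": rec.alt,
                "Variant_Classification": rec.variant_class,
                "Variant_Type": rec.variant_type,
                "Tumor_Sample_Barcode": rec.sample_id,
                "t_depth": "" if rec.t_depth is None else rec.t_depth,
                "t_alt_count": "" if rec.alt_depth is None else rec.alt_depth,
                "n_depth": "" if rec.n_depth is None else rec.n_depth,
                "HGVSp_Short": rec.protein_change,
                "gnomAD_AF": "" if rec.gnomad_af is None else rec.gnomad_af,
                "HotSpotAllele": "Yes" if rec.hotspot else "",
                "callers": ",".join(sorted(rec.callers)),
                "consensus_reason": (reasons or {}).get(rec.key, ""),
            }
        )
    return pd.DataFrame(rows, columns=MAF_REQUIRED[:9] + MAF_REQUIRED[9:] + MAF_OPTIONAL)


def write_maf(records: Sequence[VariantRecord], path, reasons: Optional[Dict] = None) -> None:
    """Write records as MAF-dialect TSV in canonical (sorted-key) order."""
    ordered = sorted(records, key=lambda r: r.key)
    variants_to_frame(ordered, reasons=reasons).to_csv(path, sep="\t", index=False)


def write_consensus_maf(consensus: Sequence[ConsensusVariant], path) -> None:
    reasons = {cv.key: cv.consensus_reason for cv in consensus}
    write_maf([cv.record for cv in consensus], path, reasons=reasons)


def read_consensus_maf(path) -> List[ConsensusVariant]:
    df = _read_tsv(path)
    records = read_maf(path)
    out = []
    reasons = list(df.get("consensus_reason", [""] * len(records)))
    for rec, reason in zip(records, reasons):
        reason = reason or ("multi_caller" if len(rec.callers) >= 2 else "hotspot_rescue")
        out.append(ConsensusVariant(record=rec, consensus_reason=reason))
    return out


def read_seg(path, caller: str, ploidy: int = 2) -> List[CnvSegment]:
    """Read a SEG-like TSV of copy-number segments.

    Columns: ``sample_id chrom start end`` plus ``copy_number`` and/or
    ``status``. Input coordinates are 0-based half-open; when only a copy
    number is given the direction status is derived from the configured
    ploidy (see :func:`pedcns.model.status_from_copy_number`).
    """
    df = _read_tsv(path)
    for col in ("sample_id", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"SEG file {path} is missing column {col!r}")
    if "copy_number" not in df.columns and "status" not in df.columns:
        raise FormatError(f"SEG file {path} needs a copy_number or status column")
    segments: List[CnvSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        start, end = int(row["start"]), int(row["end"])
        if end <= start:
            raise RowError(f"end <= start ({start}, {end})", row=i)
        cn = _opt_int(row.get("copy_number", ""), i, "copy_number")
        status = row.get("status", "").strip()
        if not status:
            if cn is None:
                raise RowError("neither status nor copy_number present", row=i)
            status = status_from_copy_number(cn, ploidy=ploidy)
        try:
            seg = CnvSegment(
                sample_id=row["sample_id"],
                interval=GenomicInterval(normalize_chrom(row["chrom"]), start, end),
                caller=caller,
                copy_number=cn,
                status=status,
            )
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: {exc}") from exc
        segments.append(seg)
    return segments


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file into a merged :class:`IntervalSet`."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {i}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0:
                raise FormatError(f"{path} line {i}: negative coordinate")
            intervals.append(GenomicInterval(normalize_chrom(chrom), start, end))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_bed(path) -> Dict[str, GenomicInterval]:
    """BED4 gene model: one interval per gene symbol (column 4)."""
    genes: Dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path} line {i}: gene BED needs 4 columns")
            genes[fields[3]] = GenomicInterval(
                normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
            )
    return genes


def read_fusions(path) -> List[FusionCall]:
    df = _read_tsv(path)
    for col in ("sample_id", "gene5", "gene3", "caller"):
        if col not in df.columns:
            raise FormatError(f"fusion file {path} is missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        annots = frozenset(a for a in row.get("annotations", "").split(",") if a)
        out.append(
            FusionCall(
                sample_id=row["sample_id"],
                gene5=row["gene5"],
                gene3=row["gene3"],
                caller=row["caller"],
                cancer_group=row.get("cancer_group", ""),
                annotations=annots,
            )
        )
    return out


def read_methyl(path) -> List[MethylPrediction]:
    df = _read_tsv(path)
    for col in ("sample_id", "classifier", "subclass", "score"):
        if col not in df.columns:
            raise FormatError(f"methylation file {path} is missing column {col!r}")
    return [
        MethylPrediction(
            sample_id=row.sample_id,
            classifier=row.classifier,
            subclass=row.subclass,
            score=float(row.score),
        )
        for row in df.itertuples(index=False)
        if row.subclass
    ]


def read_histologies(path) -> List[SpecimenRecord]:
    df = _read_tsv(path)
    for col in ("sample_id", "participant_id"):
        if col not in df.columns:
            raise FormatError(f"histologies file {path} is missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        age = row.get("age_at_diagnosis_years", "")
        out.append(
            SpecimenRecord(
                sample_id=row["sample_id"],
                participant_id=row["participant_id"],
                tumor_event_id=row.get("tumor_event_id", ""),
                experimental_strategy=row.get("experimental_strategy", ""),
                tumor_descriptor=row.get("tumor_descriptor", ""),
                pathology_diagnosis=row.get("pathology_diagnosis", ""),
                pathology_free_text_diagnosis=row.get("pathology_free_text_diagnosis", ""),
                age_at_diagnosis_years=None if age in ("", "NA") else float(age),
                germline_flags=frozenset(
                    g for g in row.get("germline_flags", "").split(",") if g
                ),
                anatomical_site=row.get("anatomical_site", ""),
                cancer_group=row.get("cancer_group", ""),
            )
        )
    return out


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: gene_id, gene_symbol, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if "gene_symbol" not in df.columns:
        raise FormatError(f"expression file {path} needs a gene_symbol column")
    value_cols = [c for c in df.columns if c not in ("gene_id", "gene_symbol")]
    df[value_cols] = df[value_cols].astype(float)
    if (df[value_cols].values < 0).any():
        raise FormatError(f"expression file {path} contains negative values")
    return df
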