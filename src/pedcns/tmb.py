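"""Tumor mutational burden from the consensus MAF.

Multi-nucleotide variants are first split into their constituent SNVs and
de-duplicated per sample. The all-mutation TMB counts every consensus
mutation inside the effectively surveyed region (for WGS, the intersection
of the callers' surveyed BEDs; for WXS, the capture BED); the coding TMB
counts only nonsynonymous classifications inside the intersection of the
surveyed region with coding sequence. The raw ratios are mutations per bp;
results are reported per megabase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Optional, Sequence

from .errors import PedcnsError, RowError
from .intervals import IntervalSet, intersect_sets
from .model import MNP_TYPES, NONSYN_CLASSES, VariantRecord

#: Alternate nonsynonymous classification set (Friends of Cancer Research TMB
#: harmonization flavor). Shipped as an editable default: the project list is
#: configuration, not a constant of the method.
FOCR_NONSYN_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
    }
)


@dataclass(frozen=True)
class TmbResult:
    """Per-sample tumor mutational burden (numerators, denominators, /Mb)."""

    sample_id: str
    strategy: str  # "WGS" | "WXS"
    numerator_all: int
    numerator_coding: int
    denominator_all: int
    denominator_coding: int

    def __post_init__(self) -> None:
        if self.denominator_all <= 0 or self.denominator_coding <= 0:
            raise PedcnsError(
                f"non-positive TMB denominator for sample {self.sample_id}"
            )

    @property
    def tmb_all(self) -> float:
        """All-mutation burden, mutations per Mb."""
        return self.numerator_all / (self.denominator_all / 1e6)

    @property
    def tmb_coding(self) -> float:
        """Coding nonsynonymous burden, mutations per Mb."""
        return self.numerator_coding / (self.denominator_coding / 1e6)


def split_mnv(variants: Sequence[VariantRecord]) -> List[VariantRecord]:
    """Split every DNP/TNP/ONP into per-base SNVs and de-duplicate per sample.

    Constituent SNVs inherit sample, classification, depths, and flags.
    A resulting SNV identical (by variant key) to an existing call is kept
    once.
    """
    seen = set()
    out: List[VariantRecord] = []
    for rec in variants:
        if rec.variant_type in MNP_TYPES:
            if len(rec.ref) != len(rec.alt) or len(rec.ref) != rec.end - rec.start + 1:
                raise RowError(
                    f"MNV ref/alt length mismatch at {rec.chrom}:{rec.start} "
                    f"{rec.ref}>{rec.alt}"
                )
            pieces = [
                replace(
                    rec,
                    start=rec.start + i,
                    end=rec.start + i,
                    ref=rec.ref[i],
                    alt=rec.alt[i],
                    variant_type="SNP",
                )
                for i in range(len(rec.ref))
            ]
        else:
            pieces = [rec]
        for piece in pieces:
            if piece.key in seen:
                continue
            seen.add(piece.key)
            out.append(piece)
    return out


def coding_denominator(surveyed: IntervalSet, cds: IntervalSet) -> int:
    """Size in bp of the surveyed-region / coding-sequence intersection."""
    bp = intersect_sets(surveyed, cds).total_bp
    if bp == 0:
        raise PedcnsError("surveyed regions and coding sequence are disjoint")
    return bp


def _in_set(rec: VariantRecord, region: IntervalSet) -> bool:
    # MAF start is 1-based inclusive; region sets are 0-based half-open.
    return region.contains_point(rec.chrom, rec.start - 1)


def compute_tmb(
    variants: Sequence[VariantRecord],
    strategy: str,
    all_region: IntervalSet,
    coding_region: IntervalSet,
    nonsyn_filter: FrozenSet[str] = NONSYN_CLASSES,
) -> List[TmbResult]:
    """TMB per sample from already-split consensus variants.

    ``all_region`` is the surveyed-area denominator region and
    ``coding_region`` its intersection with coding sequence. Variants
    outside the respective denominator region are excluded from the
    numerator; the coding numerator additionally requires a
    ``nonsyn_filter`` classification.
    """
    if strategy not in ("WGS", "WXS"):
        raise PedcnsError(f"unknown strategy {strategy!r}")
    den_all = all_region.total_bp
    den_coding = coding_region.total_bp
    by_sample: Dict[str, List[VariantRecord]] = {}
    for rec in variants:
        by_sample.setdefault(rec.sample_id, []).append(rec)

    results = []
    for sample in sorted(by_sample):
        recs = by_sample[sample]
        num_all = sum(1 for r in recs if _in_set(r, all_region))
        num_coding = sum(
            1
            for r in recs
            if r.variant_class in nonsyn_filter and _in_set(r, coding_region)
        )
        results.append(
            TmbResult(sample, strategy, num_all, num_coding, den_all, den_coding)
        )
    return results


def nonsyn_filter_focr(variants: Sequence[VariantRecord]) -> List[VariantRecord]:
    """Subset variants to the FoCR nonsynonymous classification set."""
    return [v for v in variants if v.variant_class in FOCR_NONSYN_CLASSES]


def tmb_to_frame(results: Sequence[TmbResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "strategy": r.strategy,
                "numerator_all": r.numerator_all,
                "numerator_coding": r.numerator_coding,
                "denominator_all_bp": r.denominator_all,
                "denominator_coding_bp": r.denominator_coding,
                "tmb_all_per_mb": r.tmb_all,
                "tmb_coding_per_mb": r.tmb_coding,
            }
            for r in results
        ]
    )
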