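"""Multi-caller CNV consensus and gene-level focal status.

Per sample, same-direction segments from pairs of callers enter the
consensus when they reciprocally overlap by >= 50% (the intersection
interval is emitted) or when the smaller segment is > 90% covered by the
other caller's segment (the smaller segment is emitted). Noisy
(sample, caller) files with more than 2,500 non-neutral segments are
dropped first. Consensus regions within 10 kb of each other in the same
direction are merged; regions shorter than 3 kb or overlapping a
blacklist (immunoglobulin / telomeric / centromeric / segmental
duplication regions) by >= 50% are removed. Gene-level focal status is
then assigned from region/gene overlap with a three-rule duplicate
resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .intervals import GenomicInterval, IntervalSet, reciprocal_overlap
from .model import CnvSegment, Thresholds

logger = logging.getLogger(__name__)

#: Copy-number donor order for merged/consensus regions (paper silent).
CNV_CALLER_PRIORITY = {"controlfreec": 0, "cnvkit": 1, "gatk": 2, "mantasv": 3}

#: Preference rank used by duplicate-status resolution (lower = preferred).
STATUS_RANK = {
    "amplification": 0,
    "deep deletion": 1,
    "gain": 2,
    "loss": 3,
    "neutral": 4,
}


@dataclass(frozen=True)
class ConsensusCnvRegion:
    """A consensus copy-number region supported by >= 2 callers."""

    sample_id: str
    interval: GenomicInterval
    direction: str  # "gain" | "loss"
    supporting_callers: FrozenSet[str]
    copy_number: Optional[int] = None
    extreme_status: Optional[str] = None  # "amplification" | "deep deletion"

    @property
    def status(self) -> str:
        return self.extreme_status or self.direction


@dataclass(frozen=True)
class GeneStatusCall:
    """Copy-number status of one gene in one sample."""

    sample_id: str
    gene: str
    status: str
    dominant_segment: Optional[GenomicInterval] = None
    overlap_bp: int = 0


def denoise_caller_files(
    per_caller: Dict[str, Sequence[CnvSegment]],
    thresholds: Thresholds = Thresholds(),
) -> Dict[str, List[CnvSegment]]:
    """Drop any (sample, caller) group with > 2,500 non-neutral segments."""
    out: Dict[str, List[CnvSegment]] = {}
    for caller, segments in per_caller.items():
        by_sample: Dict[str, List[CnvSegment]] = {}
        for seg in segments:
            by_sample.setdefault(seg.sample_id, []).append(seg)
        kept: List[CnvSegment] = []
        for sample, segs in by_sample.items():
            n_cnv = sum(1 for s in segs if s.direction is not None)
            if n_cnv > thresholds.max_cnv_per_file:
                logger.warning(
                    "dropping noisy CNV file: sample=%s caller=%s (%d segments)",
                    sample,
                    caller,
                    n_cnv,
                )
                continue
            kept.extend(segs)
        out[caller] = kept
    return out


def _extreme(*statuses: Optional[str]) -> Optional[str]:
    for status in ("amplification", "deep deletion"):
        if status in statuses:
            return status
    return None


def _donor_cn(a: CnvSegment, b: CnvSegment) -> Optional[int]:
    first, second = sorted(
        (a, b), key=lambda s: CNV_CALLER_PRIORITY.get(s.caller, len(CNV_CALLER_PRIORITY))
    )
    return first.copy_number if first.copy_number is not None else second.copy_number


def pairwise_consensus(
    per_caller: Dict[str, Sequence[CnvSegment]],
    thresholds: Thresholds = Thresholds(),
) -> List[ConsensusCnvRegion]:
    """Two-caller consensus regions from reciprocal overlap or containment.

    Only same-sample, same-direction segments are compared. Rule 1 emits
    the intersection of a pair with reciprocal overlap >= ``recip_overlap``
    on both sides; rule 2 emits the smaller segment when the other caller
    covers more than ``containment`` (0.9) of its length. Amplification /
    deep-deletion statuses participate as gain / loss and the extreme
    status is preserved when any supporter carried it.
    """
    by_sample_dir: Dict[tuple, Dict[str, List[CnvSegment]]] = {}
    for caller, segments in per_caller.items():
        for seg in segments:
            if seg.direction is None:
                continue
            by_sample_dir.setdefault((seg.sample_id, seg.direction), {}).setdefault(
                caller, []
            ).append(seg)

    regions: List[ConsensusCnvRegion] = []
    for (sample, direction), groups in sorted(by_sample_dir.items()):
        callers = sorted(groups)
        for i in range(len(callers)):
            for j in range(i + 1, len(callers)):
                ca, cb = callers[i], callers[j]
                for sa in groups[ca]:
                    for sb in groups[cb]:
                        frac_a, frac_b = reciprocal_overlap(sa.interval, sb.interval)
                        if frac_a == 0.0:
                            continue
                        supporters = frozenset({ca, cb})
                        extreme = _extreme(sa.status, sb.status)
                        cn = _donor_cn(sa, sb)
                        if (
                            frac_a >= thresholds.recip_overlap
                            and frac_b >= thresholds.recip_overlap
                        ):
                            interval = GenomicInterval(
                                sa.interval.chrom,
                                max(sa.interval.start, sb.interval.start),
                                min(sa.interval.end, sb.interval.end),
                            )
                            regions.append(
                                ConsensusCnvRegion(
                                    sample, interval, direction, supporters, cn, extreme
                                )
                            )
                        else:
                            smaller, frac_small = (
                                (sa, frac_a) if sa.interval.length <= sb.interval.length
                                else (sb, frac_b)
                            )
                            if frac_small > thresholds.containment:
                                regions.append(
                                    ConsensusCnvRegion(
                                        sample,
                                        smaller.interval,
                                        direction,
                                        supporters,
                                        cn,
                                        extreme,
                                    )
                                )
    regions.sort(key=lambda r: (r.sample_id, r.interval, r.direction))
    return regions


def consensus_with_fallback(
    per_caller: Dict[str, Sequence[CnvSegment]],
    gatk_available: bool = True,
    manta_segments: Sequence[CnvSegment] = (),
    thresholds: Thresholds = Thresholds(),
) -> List[ConsensusCnvRegion]:
    """Run consensus on (freec, cnvkit, gatk), or substitute MantaSV-derived
    segments as the third caller when no GATK panel of normals exists."""
    trio = {
        c: list(v)
        for c, v in per_caller.items()
        if c in ("controlfreec", "cnvkit", "gatk")
    }
    if not gatk_available:
        trio.pop("gatk", None)
        trio["mantasv"] = list(manta_segments)
    with_data = [c for c, v in trio.items() if v]
    if len(with_data) < 2:
        logger.warning("fewer than two CNV callers with data; empty consensus")
        return []
    return pairwise_consensus(trio, thresholds)


def merge_adjacent(
    regions: Sequence[ConsensusCnvRegion],
    thresholds: Thresholds = Thresholds(),
) -> List[ConsensusCnvRegion]:
    """Merge same-direction regions of one sample within ``merge_gap`` bp.

    Overlapping regions (negative gap) merge too; supporters are unioned,
    the extreme status survives if any constituent carried it, and the
    copy number is taken from the first constituent in coordinate order.
    """
    grouped: Dict[tuple, List[ConsensusCnvRegion]] = {}
    for region in regions:
        grouped.setdefault(
            (region.sample_id, region.direction, region.interval.chrom), []
        ).append(region)

    out: List[ConsensusCnvRegion] = []
    for key in sorted(grouped):
        members = sorted(grouped[key], key=lambda r: (r.interval.start, r.interval.end))
        current = members[0]
        for nxt in members[1:]:
            gap = nxt.interval.start - current.interval.end
            if gap <= thresholds.merge_gap:
                current = ConsensusCnvRegion(
                    current.sample_id,
                    GenomicInterval(
                        current.interval.chrom,
                        current.interval.start,
                        max(current.interval.end, nxt.interval.end),
                    ),
                    current.direction,
                    current.supporting_callers | nxt.supporting_callers,
                    current.copy_number
                    if current.copy_number is not None
                    else nxt.copy_number,
                    _extreme(current.extreme_status, nxt.extreme_status),
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    out.sort(key=lambda r: (r.sample_id, r.interval, r.direction))
    return out


def blacklist_and_size_filter(
    regions: Sequence[ConsensusCnvRegion],
    blacklist: Optional[IntervalSet] = None,
    thresholds: Thresholds = Thresholds(),
) -> List[ConsensusCnvRegion]:
    """Remove regions shorter than ``min_cnv_len`` bp or with >=
    ``blacklist_overlap`` of their length inside the blacklist."""
    if blacklist is None:
        logger.warning("no blacklist supplied; applying size filter only")
    kept = []
    for region in regions:
        if region.interval.length < thresholds.min_cnv_len:
            continue
        if blacklist is not None:
            frac = blacklist.overlap_bp(region.interval) / region.interval.length
            if frac >= thresholds.blacklist_overlap:
                continue
        kept.append(region)
    return kept


def run_cnv_consensus(
    per_caller: Dict[str, Sequence[CnvSegment]],
    blacklist: Optional[IntervalSet] = None,
    gatk_available: bool = True,
    manta_segments: Sequence[CnvSegment] = (),
    thresholds: Thresholds = Thresholds(),
) -> List[ConsensusCnvRegion]:
    """Full consensus stage: de-noise, pairwise consensus, merge, filter."""
    per_caller = denoise_caller_files(per_caller, thresholds)
    regions = consensus_with_fallback(
        per_caller, gatk_available, manta_segments, thresholds
    )
    regions = merge_adjacent(regions, thresholds)
    return blacklist_and_size_filter(regions, blacklist, thresholds)


def neutral_to_na(segments: Sequence[CnvSegment], samples_in_consensus) -> List[CnvSegment]:
    """Set copy_number to NA (None) on neutral segments of consensus samples."""
    out = []
    for seg in segments:
        if seg.status == "neutral" and seg.sample_id in samples_in_consensus:
            seg = replace(seg, copy_number=None)
        out.append(seg)
    return out


def append_wxs_calls(consensus_rows, wxs_cnvkit_rows):
    """Concatenate WXS CNVkit rows (flagged non-consensus) onto the table."""
    import pandas as pd

    if len(wxs_cnvkit_rows) == 0:
        return consensus_rows.copy()
    wxs = wxs_cnvkit_rows.copy()
    wxs["in_consensus"] = False
    if "caller" not in wxs.columns:
        wxs["caller"] = "cnvkit"
    combined = pd.concat([consensus_rows, wxs], ignore_index=True)
    return combined[consensus_rows.columns]


def regions_to_frame(regions: Sequence[ConsensusCnvRegion]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "status": r.status,
                "direction": r.direction,
                "copy_number": "NA" if r.copy_number is None else r.copy_number,
                "callers": ",".join(sorted(r.supporting_callers)),
                "caller": "consensus",
                "in_consensus": True,
            }
            for r in regions
        ],
        columns=[
            "sample_id",
            "chrom",
            "start",
            "end",
            "status",
            "direction",
            "copy_number",
            "callers",
            "caller",
            "in_consensus",
        ],
    )


def assign_gene_status(
    regions: Sequence[ConsensusCnvRegion],
    gene_model: Dict[str, GenomicInterval],
    samples: Optional[Iterable[str]] = None,
) -> List[GeneStatusCall]:
    """One status call per (sample, gene, overlapping region); genes with no
    overlapping region get a single neutral call (absence of a consensus
    region is absence of evidence for change)."""
    if samples is None:
        samples = sorted({r.sample_id for r in regions})
    by_sample: Dict[str, List[ConsensusCnvRegion]] = {}
    for region in regions:
        by_sample.setdefault(region.sample_id, []).append(region)

    calls: List[GeneStatusCall] = []
    for sample in samples:
        for gene, g_iv in sorted(gene_model.items()):
            hits = []
            for region in by_sample.get(sample, []):
                ov = region.interval.overlap_bp(g_iv)
                if ov > 0:
                    hits.append(
                        GeneStatusCall(sample, gene, region.status, region.interval, ov)
                    )
            if hits:
                calls.extend(hits)
            else:
                calls.append(GeneStatusCall(sample, gene, "neutral"))
    return calls


def resolve_duplicate_status(calls: Sequence[GeneStatusCall]) -> List[GeneStatusCall]:
    """Resolve conflicting per-gene status calls to exactly one.

    Priority: 1) non-neutral over neutral; 2) the call whose segment
    overlaps the gene most; 3) amplification over gain and deep deletion
    over loss; remaining ties broken deterministically by (status rank,
    segment start).
    """
    grouped: Dict[tuple, List[GeneStatusCall]] = {}
    for call in calls:
        grouped.setdefault((call.sample_id, call.gene), []).append(call)

    resolved = []
    for key in sorted(grouped):
        group = grouped[key]
        non_neutral = [c for c in group if c.status != "neutral"]
        if non_neutral:
            group = non_neutral
        best = min(
            group,
            key=lambda c: (
                -c.overlap_bp,
                STATUS_RANK.get(c.status, len(STATUS_RANK)),
                c.dominant_segment.start if c.dominant_segment else 0,
            ),
        )
        resolved.append(best)
    return resolved


def gene_status_to_frame(calls: Sequence[GeneStatusCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "status": c.status,
                "segment": (
                    f"{c.dominant_segment.chrom}:{c.dominant_segment.start}-"
                    f"{c.dominant_segment.end}"
                    if c.dominant_segment
                    else ""
                ),
                "overlap_bp": c.overlap_bp,
            }
            for c in calls
        ],
        columns=["sample_id", "gene", "status", "segment", "overlap_bp"],
    )
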