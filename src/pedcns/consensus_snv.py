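"""Multi-caller somatic SNV/indel consensus.

Four callers' MAFs are merged on the variant identity key
``(sample, chrom, start, end, ref, alt)``. A call is retained when at
least two callers report it, or when any caller flags it as a hotspot
allele. Strelka2 reports multi-nucleotide substitutions as runs of
adjacent SNPs, so before merging, any MNP reported by another caller whose
every base is supported by consecutive Strelka2 SNPs is reconstructed into
a single Strelka2 MNP call. Finally, likely germline leakage (shallow
normal coverage plus population frequency) is removed, and tumor-only
inputs pass a minimal-depth filter.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Dict, Iterable, List, Sequence

from .model import (
    MNP_TYPES,
    SNV_CALLERS,
    ConsensusVariant,
    Thresholds,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: Depth/annotation donor order when callers disagree on a shared key.
CALLER_PRIORITY = {name: rank for rank, name in enumerate(SNV_CALLERS)}


def _mnp_type(length: int) -> str:
    return {2: "DNP", 3: "TNP"}.get(length, "ONP")


def reconstruct_mnp(
    strelka_calls: Sequence[VariantRecord],
    other_caller_mnps: Sequence[VariantRecord],
) -> List[VariantRecord]:
    """Convert Strelka2 SNP runs supported by another caller's MNP into MNPs.

    A candidate MNP claims Strelka2 SNPs only if every constituent base is
    matched (same sample/chrom/position/ref/alt) and none of those SNPs is
    already claimed. Conflicting candidates are resolved longest first,
    then leftmost, to keep merges maximal. Unmatched SNPs pass through.
    """
    snp_index: Dict[tuple, VariantRecord] = {}
    for rec in strelka_calls:
        if rec.variant_type == "SNP":
            snp_index[(rec.sample_id, rec.chrom, rec.start, rec.ref, rec.alt)] = rec

    # Deduplicate candidates across callers by span+alleles.
    candidates: Dict[tuple, VariantRecord] = {}
    for rec in other_caller_mnps:
        if rec.variant_type not in MNP_TYPES:
            continue
        if len(rec.ref) != len(rec.alt) or len(rec.ref) != rec.end - rec.start + 1:
            continue
        candidates.setdefault(
            (rec.sample_id, rec.chrom, rec.start, rec.ref, rec.alt), rec
        )

    claimed: set = set()
    merged: List[VariantRecord] = []
    ordered = sorted(
        candidates.values(),
        key=lambda r: (-len(r.ref), r.chrom, r.start, r.sample_id, r.alt),
    )
    for cand in ordered:
        member_keys = []
        for offset in range(len(cand.ref)):
            key = (
                cand.sample_id,
                cand.chrom,
                cand.start + offset,
                cand.ref[offset],
                cand.alt[offset],
            )
            if key not in snp_index or key in claimed:
                member_keys = None
                break
            member_keys.append(key)
        if not member_keys:
            continue
        claimed.update(member_keys)
        donor = snp_index[member_keys[0]]  # leftmost member donates depths
        merged.append(
            replace(
                donor,
                start=cand.start,
                end=cand.end,
                ref=cand.ref,
                alt=cand.alt,
                variant_type=_mnp_type(len(cand.ref)),
                variant_class=cand.variant_class or donor.variant_class,
                hotspot=donor.hotspot or cand.hotspot,
            )
        )

    out: List[VariantRecord] = []
    for rec in strelka_calls:
        if (
            rec.variant_type == "SNP"
            and (rec.sample_id, rec.chrom, rec.start, rec.ref, rec.alt) in claimed
        ):
            continue
        out.append(rec)
    out.extend(merged)
    out.sort(key=lambda r: r.key)
    return out


def call_consensus(
    per_caller: Dict[str, Sequence[VariantRecord]],
    thresholds: Thresholds = Thresholds(),
) -> List[ConsensusVariant]:
    """Retain variants seen by >= ``min_callers`` callers or hotspot-flagged.

    Strelka2 input is expected to have gone through
    :func:`reconstruct_mnp` already. The record emitted for a shared key
    takes depths and annotations from the highest-priority caller
    (strelka2 > mutect2 > lancet > vardict); the ``callers`` field is the
    union of supporters and ``hotspot`` the OR over supporters.
    """
    grouped: Dict[tuple, List[tuple[str, VariantRecord]]] = {}
    for caller, records in per_caller.items():
        for rec in records:
            grouped.setdefault(rec.key, []).append((caller, rec))

    out: List[ConsensusVariant] = []
    for key in sorted(grouped):
        entries = grouped[key]
        callers = frozenset(c for c, _ in entries)
        hotspot = any(r.hotspot for _, r in entries)
        if len(callers) < thresholds.min_callers and not hotspot:
            continue
        reason = (
            "multi_caller" if len(callers) >= thresholds.min_callers else "hotspot_rescue"
        )
        donor_caller, donor = min(
            entries, key=lambda cr: CALLER_PRIORITY.get(cr[0], len(CALLER_PRIORITY))
        )
        record = replace(donor, callers=callers, hotspot=hotspot)
        members: tuple = ()
        if record.variant_type in MNP_TYPES and len(record.ref) == len(record.alt):
            members = tuple(
                (
                    record.sample_id,
                    record.chrom,
                    record.start + i,
                    record.start + i,
                    record.ref[i],
                    record.alt[i],
                )
                for i in range(len(record.ref))
            )
        out.append(
            ConsensusVariant(
                record=record, consensus_reason=reason, mnp_members=members
            )
        )
    return out


def filter_germline_leakage(
    variants: Sequence[ConsensusVariant],
    thresholds: Thresholds = Thresholds(),
) -> List[ConsensusVariant]:
    """Drop probable germline leakage from the consensus.

    A variant is removed iff it is not hotspot-flagged, its matched-normal
    depth is <= ``normal_depth_max`` (default 7 reads), and its gnomAD
    population allele frequency exceeds ``gnomad_af_min`` (default 0.001).
    Absent normal depth (tumor-only) or absent gnomAD AF never triggers
    removal.
    """
    kept = []
    for cv in variants:
        rec = cv.record
        if (
            not rec.hotspot
            and rec.n_depth is not None
            and rec.n_depth <= thresholds.normal_depth_max
            and rec.gnomad_af is not None
            and rec.gnomad_af > thresholds.gnomad_af_min
        ):
            continue
        kept.append(cv)
    return kept


def filter_tumor_only(
    variants: Sequence[VariantRecord],
    thresholds: Thresholds = Thresholds(),
) -> List[VariantRecord]:
    """Depth filter for tumor-only calls: drop alt_depth == 0 or t_depth < 4."""
    kept = []
    for rec in variants:
        if rec.alt_depth is None or rec.t_depth is None:
            logger.warning(
                "variant %s has absent depths; retained in tumor-only filter", rec.key
            )
            kept.append(rec)
            continue
        if rec.alt_depth == 0 or rec.t_depth < thresholds.tumor_only_min_t_depth:
            continue
        kept.append(rec)
    return kept


def run_consensus(
    per_caller: Dict[str, Sequence[VariantRecord]],
    thresholds: Thresholds = Thresholds(),
) -> List[ConsensusVariant]:
    """Full consensus stage: MNP reconstruction, merge, germline filter."""
    per_caller = {c: list(v) for c, v in per_caller.items()}
    if "strelka2" in per_caller:
        other_mnps = [
            rec
            for caller, recs in per_caller.items()
            if caller != "strelka2"
            for rec in recs
            if rec.variant_type in MNP_TYPES
        ]
        per_caller["strelka2"] = reconstruct_mnp(per_caller["strelka2"], other_mnps)
    consensus = call_consensus(per_caller, thresholds)
    return filter_germline_leakage(consensus, thresholds)
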