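"""Chromosome-arm-level gain/loss events from consensus CNV regions.

An arm is called gained (lost) when the merged same-direction consensus
regions of a sample cover at least ``arm_event_min_fraction`` (default
0.5) of the arm's length.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

from ..consensus_cnv import ConsensusCnvRegion
from ..errors import FormatError
from ..intervals import GenomicInterval, IntervalSet
from ..model import Thresholds, normalize_chrom


def read_arm_table(path) -> Dict[str, GenomicInterval]:
    """TSV with columns arm, chrom, start, end (0-based half-open)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("arm", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"arm table {path} is missing column {col!r}")
    return {
        row.arm: GenomicInterval(normalize_chrom(row.chrom), int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    }


def call_arm_events(
    regions: Sequence[ConsensusCnvRegion],
    arms: Dict[str, GenomicInterval],
    thresholds: Thresholds = Thresholds(),
) -> Dict[str, Set[Tuple[str, str]]]:
    """Per-sample set of (arm, direction) events.

    Same-direction region intervals are merged per sample before measuring
    arm coverage, so overlapping consensus regions are not double counted.
    Regions on chromosomes absent from the arm table are ignored.
    """
    known_chroms = {iv.chrom for iv in arms.values()}
    by_sample_dir: Dict[Tuple[str, str], List[GenomicInterval]] = {}
    samples = set()
    for region in regions:
        samples.add(region.sample_id)
        if region.interval.chrom not in known_chroms:
            continue
        by_sample_dir.setdefault((region.sample_id, region.direction), []).append(
            region.interval
        )

    events: Dict[str, Set[Tuple[str, str]]] = {s: set() for s in samples}
    for (sample, direction), intervals in by_sample_dir.items():
        merged = IntervalSet(intervals)
        for arm, arm_iv in arms.items():
            covered = merged.overlap_bp(arm_iv)
            if covered / arm_iv.length >= thresholds.arm_event_min_fraction:
                events[sample].add((arm, direction))
    return events
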