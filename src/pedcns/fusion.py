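"""Fusion prioritization: oncogenic annotation and retention rules.

Operates on already artifact-filtered fusion calls from the two RNA
callers (Arriba, STAR-Fusion). A fusion is annotated putative-oncogenic
when either partner gene is a known kinase, oncogene, tumor suppressor,
curated transcription factor, on the COSMIC Cancer Gene Census, or
observed in TCGA. A call is retained when the pair was called by both
callers in the same sample, is recurrent within one cancer group, is
specific to a single cancer group cohort-wide, or carries the oncogenic
annotation. Clinical panel (DGD) calls bypass filtering entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from .model import FusionCall, Thresholds

ONCOGENIC_FLAGS = (
    "kinase",
    "oncogene",
    "tumor_suppressor",
    "transcription_factor",
    "cosmic_census",
    "tcga_observed",
)


@dataclass(frozen=True)
class PrioritizedFusion:
    """A retained fusion call with the reasons it survived filtering."""

    call: FusionCall
    putative_oncogenic: bool
    retained_reason: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.retained_reason:
            raise ValueError("retained fusion must carry at least one reason")


def annotate_oncogenic(
    fusions: Sequence[FusionCall], gene_lists: Dict[str, Set[str]]
) -> List[FusionCall]:
    """Add annotation flags: flag present iff gene5 or gene3 is on that list."""
    out = []
    for call in fusions:
        flags = set(call.annotations)
        for flag, genes in gene_lists.items():
            if call.gene5 in genes or call.gene3 in genes:
                flags.add(flag)
        out.append(
            FusionCall(
                sample_id=call.sample_id,
                gene5=call.gene5,
                gene3=call.gene3,
                caller=call.caller,
                cancer_group=call.cancer_group,
                annotations=frozenset(flags),
            )
        )
    return out


def retain_fusions(
    fusions: Sequence[FusionCall],
    thresholds: Thresholds = Thresholds(),
) -> List[PrioritizedFusion]:
    """Apply the four retention rules; DGD panel calls pass through.

    "Recurrent" means the gene pair is seen in >= ``fusion_recurrence_min``
    distinct samples of one cancer group; "cancer-group specific" means
    the pair occurs in exactly one cancer group cohort-wide. Output order
    is deterministic and independent of input row order.
    """
    pair_samples_by_group: Dict[Tuple[str, str, str], Set[str]] = {}
    pair_groups: Dict[Tuple[str, str], Set[str]] = {}
    pair_sample_callers: Dict[Tuple[str, str, str], Set[str]] = {}
    for call in fusions:
        if call.caller == "dgd_panel":
            continue
        pair_samples_by_group.setdefault(
            (call.gene5, call.gene3, call.cancer_group), set()
        ).add(call.sample_id)
        pair_groups.setdefault(call.pair, set()).add(call.cancer_group)
        pair_sample_callers.setdefault(
            (call.gene5, call.gene3, call.sample_id), set()
        ).add(call.caller)

    retained: List[PrioritizedFusion] = []
    for call in sorted(
        fusions, key=lambda c: (c.sample_id, c.gene5, c.gene3, c.caller)
    ):
        if call.caller == "dgd_panel":
            retained.append(
                PrioritizedFusion(call, False, frozenset({"clinical_panel"}))
            )
            continue
        reasons = set()
        oncogenic = any(flag in call.annotations for flag in ONCOGENIC_FLAGS)
        callers_here = pair_sample_callers[(call.gene5, call.gene3, call.sample_id)]
        if {"arriba", "starfusion"} <= callers_here:
            reasons.add("both_callers")
        n_samples = len(
            pair_samples_by_group.get(
                (call.gene5, call.gene3, call.cancer_group), set()
            )
        )
        if n_samples >= thresholds.fusion_recurrence_min:
            reasons.add("recurrent")
        if len(pair_groups[call.pair]) == 1:
            reasons.add("cancer_group_specific")
        if oncogenic:
            reasons.add("oncogenic_annotation")
        if reasons:
            retained.append(PrioritizedFusion(call, oncogenic, frozenset(reasons)))
    return retained


def fusions_to_frame(fusions: Sequence[PrioritizedFusion]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": f.call.sample_id,
                "gene5": f.call.gene5,
                "gene3": f.call.gene3,
                "caller": f.call.caller,
                "cancer_group": f.call.cancer_group,
                "annotations": ",".join(sorted(f.call.annotations)),
                "putative_oncogenic": f.putative_oncogenic,
                "retained_reason": ",".join(sorted(f.retained_reason)),
            }
            for f in fusions
        ],
        columns=[
            "sample_id",
            "gene5",
            "gene3",
            "caller",
            "cancer_group",
            "annotations",
            "putative_oncogenic",
            "retained_reason",
        ],
    )
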