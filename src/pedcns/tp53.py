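"""TP53 status per tumor event: activated, lost, or other.

Evidence comes from consensus SNVs (protein changes and hotspot flags),
gene-level copy-number loss, structural variants hitting TP53, annotated
pathogenic germline variants linked to Li-Fraumeni syndrome, and an
externally trained RNA-based TP53 inactivation classifier score.

A tumor is *activated* when it carries one of the two known
gain-of-function substitutions (p.R273C, p.R248W). Otherwise it is *lost*
when any of these holds: (i) a hotspot TP53 mutation; (ii) two distinct
TP53 alterations (SNV/CNV/SV) consistent with biallelic inactivation;
(iii) a single somatic TP53 variant or a pathogenic germline LFS variant;
(iv) a germline LFS variant together with an inactivation classifier
score > 0.5. Activated takes precedence: the gain-of-function residues
are themselves hotspots and would otherwise also satisfy (i).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .model import Thresholds, Tp53Status

GOF_PROTEIN_CHANGES = ("p.R273C", "p.R248W")


@dataclass(frozen=True)
class SomaticTp53Variant:
    """One somatic TP53 small variant relevant to status calling."""

    protein_change: str = ""
    hotspot: bool = False
    domain: str = ""


@dataclass(frozen=True)
class Tp53Evidence:
    """Assembled TP53 evidence for one tumor event."""

    sample_id: str
    somatic_variants: Tuple[SomaticTp53Variant, ...] = ()
    cnv_loss: bool = False
    sv: bool = False
    germline_lfs_variant: bool = False
    classifier_score: Optional[float] = None


def classify_tp53(
    evidence: Tp53Evidence, thresholds: Thresholds = Thresholds()
) -> Tp53Status:
    """Classify one tumor event; returns status plus the fired conditions."""
    trace: List[str] = []

    if any(
        v.protein_change in GOF_PROTEIN_CHANGES for v in evidence.somatic_variants
    ):
        trace.append("gain_of_function_mutation")
        return Tp53Status(evidence.sample_id, "activated", tuple(trace))

    if any(v.hotspot for v in evidence.somatic_variants):
        trace.append("i_hotspot_mutation")
    n_alterations = (
        len(evidence.somatic_variants)
        + int(evidence.cnv_loss)
        + int(evidence.sv)
    )
    if n_alterations >= 2:
        trace.append("ii_two_distinct_alterations")
    if len(evidence.somatic_variants) >= 1 or evidence.germline_lfs_variant:
        trace.append("iii_single_somatic_or_germline_lfs")
    if (
        evidence.germline_lfs_variant
        and evidence.classifier_score is not None
        and evidence.classifier_score > thresholds.tp53_score_cutoff
    ):
        trace.append("iv_germline_lfs_plus_classifier")

    if trace:
        return Tp53Status(evidence.sample_id, "lost", tuple(trace))
    return Tp53Status(evidence.sample_id, "other", ())


def classify_cohort(
    cohort: Sequence[Tp53Evidence], thresholds: Thresholds = Thresholds()
) -> List[Tp53Status]:
    return [classify_tp53(ev, thresholds) for ev in cohort]


def tp53_to_frame(statuses: Sequence[Tp53Status]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "tp53_status": s.status,
                "evidence_trace": ",".join(s.evidence_trace),
            }
            for s in statuses
        ],
        columns=["sample_id", "tp53_status", "evidence_trace"],
    )
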