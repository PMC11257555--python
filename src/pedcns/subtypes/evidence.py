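"""Per tumor event evidence bundle and its predicate helpers.

Every evidence channel is optional; predicates on an absent channel
evaluate False, so events with partial platform coverage degrade
gracefully instead of erroring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from ..fusion import PrioritizedFusion
from ..model import (
    ConsensusVariant,
    MethylPrediction,
    SpecimenRecord,
    Thresholds,
    Tp53Status,
)


def high_confidence(
    methyl: Optional[MethylPrediction], thresholds: Thresholds = Thresholds()
) -> bool:
    """True iff a methylation prediction exists with score >= 0.8."""
    return methyl is not None and methyl.score >= thresholds.methyl_confidence


@dataclass
class EvidenceBundle:
    """All evidence channels assembled for one tumor event."""

    specimen: SpecimenRecord
    variants: List[ConsensusVariant] = field(default_factory=list)
    gene_status: Dict[str, str] = field(default_factory=dict)
    arm_events: Set[Tuple[str, str]] = field(default_factory=set)
    fusions: List[PrioritizedFusion] = field(default_factory=list)
    expr_over: Set[str] = field(default_factory=set)
    expr_under: Set[str] = field(default_factory=set)
    mycn_tpm: Optional[float] = None
    methyl: List[MethylPrediction] = field(default_factory=list)
    tp53: Optional[Tp53Status] = None
    rna_mb_label: str = ""
    prior_subtype: str = ""
    thresholds: Thresholds = field(default_factory=Thresholds)

    # -- methylation -----------------------------------------------------

    def _dkfz(self) -> Optional[MethylPrediction]:
        for pred in self.methyl:
            if pred.classifier == "dkfz_v12":
                return pred
        return self.methyl[0] if self.methyl else None

    @property
    def methyl_subclass(self) -> str:
        pred = self._dkfz()
        return pred.subclass if pred else ""

    @property
    def methyl_score(self) -> Optional[float]:
        pred = self._dkfz()
        return pred.score if pred else None

    def methyl_high_conf(self) -> bool:
        return high_confidence(self._dkfz(), self.thresholds)

    def methyl_is(self, *subclasses: str) -> bool:
        """High-confidence prediction with an exact subclass match."""
        return self.methyl_high_conf() and self.methyl_subclass in subclasses

    def methyl_contains(self, *fragments: str) -> bool:
        """High-confidence prediction whose subclass contains a fragment."""
        if not self.methyl_high_conf():
            return False
        return any(frag in self.methyl_subclass for frag in fragments)

    # -- small variants --------------------------------------------------

    def has_mutation(
        self,
        genes: Iterable[str],
        protein_changes: Optional[Iterable[str]] = None,
        classes: Optional[Iterable[str]] = None,
        hotspot: Optional[bool] = None,
    ) -> bool:
        genes = set(genes)
        changes = set(protein_changes) if protein_changes is not None else None
        classes = set(classes) if classes is not None else None
        for cv in self.variants:
            rec = cv.record
            if rec.gene not in genes:
                continue
            if changes is not None and rec.protein_change not in changes:
                continue
            if classes is not None and rec.variant_class not in classes:
                continue
            if hotspot is not None and rec.hotspot != hotspot:
                continue
            return True
        return False

    # -- copy number -----------------------------------------------------

    def gene_cn(self, gene: str) -> str:
        return self.gene_status.get(gene, "neutral")

    def gene_cn_in(self, gene: str, statuses: Iterable[str]) -> bool:
        return self.gene_cn(gene) in set(statuses)

    def has_arm_event(self, arm: str, direction: str) -> bool:
        return (arm, direction) in self.arm_events

    # -- fusions ---------------------------------------------------------

    def fusion_calls(self):
        for pf in self.fusions:
            yield pf.call

    def has_fusion_partner(self, genes: Iterable[str]) -> bool:
        genes = set(genes)
        return any(
            call.gene5 in genes or call.gene3 in genes for call in self.fusion_calls()
        )

    def has_fusion_pair(self, pairs: Iterable[Sequence[str]]) -> bool:
        """Unordered gene-pair match."""
        wanted = {frozenset(p) for p in pairs}
        return any(
            frozenset((call.gene5, call.gene3)) in wanted
            for call in self.fusion_calls()
        )

    # -- expression ------------------------------------------------------

    def over_expressed(self, gene: str) -> bool:
        return gene in self.expr_over

    def under_expressed(self, gene: str) -> bool:
        return gene in self.expr_under

    # -- clinical --------------------------------------------------------

    @property
    def age(self) -> Optional[float]:
        return self.specimen.age_at_diagnosis_years

    def free_text_contains(self, *fragments: str) -> bool:
        text = self.specimen.pathology_free_text_diagnosis.lower()
        return any(frag.lower() in text for frag in fragments)

    def location_contains(self, fragment: str) -> bool:
        return fragment.lower() in self.specimen.anatomical_site.lower()

    def has_germline_flag(self, *flags: str) -> bool:
        return any(f in self.specimen.germline_flags for f in flags)
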