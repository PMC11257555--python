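"""Selection of one independent biospecimen per participant.

Analyses that assume independent observations must not mix multiple
biospecimens from the same participant. Given an analysis-specific policy
(allowed experimental strategies, an ordered tumor-descriptor preference,
and a deterministic tie-break), this module picks exactly one qualifying
specimen per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .model import SpecimenRecord

DEFAULT_DESCRIPTOR_PREFERENCE = (
    "Initial CNS Tumor",
    "Primary Tumor",
    "Progressive",
    "Recurrence",
)


@dataclass(frozen=True)
class SelectionPolicy:
    """Filters and preferences for independent-specimen selection."""

    strategy_filter: Tuple[str, ...] = ()
    descriptor_preference: Tuple[str, ...] = DEFAULT_DESCRIPTOR_PREFERENCE
    tie_break: str = "sample_id"


def select_independent(
    specimens: Sequence[SpecimenRecord],
    policy: SelectionPolicy = SelectionPolicy(),
) -> List[SpecimenRecord]:
    """One specimen per participant, by descriptor preference then tie-break.

    Specimens failing the strategy filter are excluded; participants with
    no qualifying specimen are omitted. Descriptors not in the preference
    list rank after all listed ones. Idempotent and order-independent.
    """
    rank = {d: i for i, d in enumerate(policy.descriptor_preference)}
    worst = len(policy.descriptor_preference)
    by_participant = {}
    for spec in specimens:
        if policy.strategy_filter and spec.experimental_strategy not in policy.strategy_filter:
            continue
        by_participant.setdefault(spec.participant_id, []).append(spec)
    chosen = []
    for participant in sorted(by_participant):
        best = min(
            by_participant[participant],
            key=lambda s: (rank.get(s.tumor_descriptor, worst), s.sample_id),
        )
        chosen.append(best)
    return chosen
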