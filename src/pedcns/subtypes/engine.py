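"""Dispatch of tumor events to histology rule sets."""

from __future__ import annotations

import logging
from typing import Any, Callable, Dict, List, Optional, Sequence

from ..model import SubtypeResult
from .evidence import EvidenceBundle
from .histologies import (
    subtype_atrt,
    subtype_cranio,
    subtype_epn,
    subtype_etmr,
    subtype_hgg,
    subtype_lgg,
    subtype_mb,
    subtype_nbl,
    subtype_pb,
)
from .ruleconfig import DEFAULT_RULES

logger = logging.getLogger(__name__)

RULE_SETS: Dict[str, Callable] = {
    "hgg": subtype_hgg,
    "atrt": subtype_atrt,
    "nbl": subtype_nbl,
    "cranio": subtype_cranio,
    "epn": subtype_epn,
    "lgg": subtype_lgg,
    "mb": subtype_mb,
    "pb": subtype_pb,
    "etmr": subtype_etmr,
}


def dispatch_histology(
    pathology_diagnosis: str, rules: Dict[str, Any] = DEFAULT_RULES
) -> Optional[str]:
    """Histology rule-set key for a pathology diagnosis, or None."""
    diagnosis = pathology_diagnosis.lower()
    for key, keywords in rules["dispatch"].items():
        if any(kw in diagnosis for kw in keywords):
            return key
    return None


def run_subtyping(
    bundles: Sequence[EvidenceBundle],
    rules: Dict[str, Any] = DEFAULT_RULES,
) -> List[SubtypeResult]:
    """One :class:`SubtypeResult` per tumor event, in input order.

    Events whose pathology diagnosis matches no covered histology get
    ``molecular_subtype=None``. Results are deterministic and independent
    of cohort composition: each bundle is classified in isolation.
    """
    results = []
    for bundle in bundles:
        key = dispatch_histology(bundle.specimen.pathology_diagnosis, rules)
        if key is None:
            results.append(
                SubtypeResult(
                    tumor_event_id=bundle.specimen.tumor_event_id
                    or bundle.specimen.sample_id,
                    molecular_subtype=None,
                    fired_rules=["histology_not_covered"],
                )
            )
            continue
        results.append(RULE_SETS[key](bundle, rules))
    return results


def results_to_frame(results: Sequence[SubtypeResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "tumor_event_id": r.tumor_event_id,
                "molecular_subtype": "" if r.molecular_subtype is None else r.molecular_subtype,
                "fired_rules": ",".join(r.fired_rules),
                "review_flag": r.review_flag,
            }
            for r in results
        ],
        columns=["tumor_event_id", "molecular_subtype", "fired_rules", "review_flag"],
    )
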