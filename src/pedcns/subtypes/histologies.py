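"""Per-histology WHO 2021 research-grade subtyping rules.

Within each histology the listed criteria are an ordered priority list:
the first matching rule wins. Confidence-gated methylation evidence means
a classifier score >= 0.8; lower-scoring predictions never fire a
methylation rule. Every fall-through ends in ", To be classified" (or the
unrefined "MB, SHH" parent label for SHH medulloblastomas with no
subgroup evidence).
"""

from __future__ import annotations

from typing import Any, Dict, List, Optional, Tuple

from ..model import LOF_CLASSES, SubtypeResult
from .evidence import EvidenceBundle
from .ruleconfig import DEFAULT_RULES


def _result(bundle: EvidenceBundle, label: Optional[str], rules_fired: List[str],
            notes: str = "", review: bool = False) -> SubtypeResult:
    event = bundle.specimen.tumor_event_id or bundle.specimen.sample_id
    return SubtypeResult(
        tumor_event_id=event,
        molecular_subtype=label,
        fired_rules=rules_fired,
        confidence_notes=notes,
        review_flag=review,
    )


# ---------------------------------------------------------------------------
# High-grade glioma (including infant-type hemispheric glioma branch)
# ---------------------------------------------------------------------------

def _ihg_gate(bundle: EvidenceBundle, cfg: Dict[str, Any]) -> bool:
    # the IHG gate uses the classifier label itself, without a score gate
    return bundle.methyl_subclass == "IHG" or bundle.free_text_contains(
        *cfg["ihg_free_text"]
    )


def subtype_ihg(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    """Infant-type hemispheric glioma: suffix from the RTK fusion partner."""
    cfg = rules["hgg"]
    prefix = cfg["labels"]["ihg_prefix"]
    for suffix, partners in cfg["rtk_partners"].items():
        if bundle.has_fusion_partner(partners):
            return _result(bundle, f"{prefix}, {suffix}-altered", [f"ihg_{suffix.lower()}_fusion"])
    return _result(bundle, f"{prefix}, To be classified", ["ihg_no_rtk_fusion"])


def subtype_hgg(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["hgg"]
    labels = cfg["labels"]
    result = None

    if bundle.has_mutation(cfg["histone_genes"], protein_changes=cfg["k28_changes"]):
        result = _result(bundle, labels["dmg"], ["hgg_dmg_k28_mutation"])
    elif bundle.methyl_contains(*cfg["dmg_methyl_contains"]):
        result = _result(bundle, labels["dmg"], ["hgg_dmg_methylation"])
    elif bundle.methyl_is(*cfg["oligo_idh_classes"]):
        result = _result(bundle, labels["oligo_idh"], ["hgg_oligo_idh_methylation"])
    elif bundle.methyl_is(*cfg["oligosarcoma_classes"]):
        result = _result(bundle, labels["oligosarcoma"], ["hgg_oligosarcoma_methylation"])
    elif (
        (bundle.methyl_is("PXA") or bundle.free_text_contains(*cfg["pxa_free_text"]))
        and bundle.has_mutation(["BRAF"], protein_changes=["p.V600E"])
        and (
            bundle.gene_cn_in("CDKN2A", ["deep deletion"])
            or bundle.gene_cn_in("CDKN2B", ["deep deletion"])
        )
    ):
        result = _result(bundle, labels["pxa"], ["hgg_pxa"])
    elif bundle.methyl_is(*cfg["dhg_classes"]):
        result = _result(bundle, labels["dhg"], ["hgg_dhg_g35_methylation"])
    elif bundle.methyl_is(*cfg["hgg_idh_classes"]):
        result = _result(bundle, labels["hgg_idh"], ["hgg_idh_methylation"])
    elif bundle.methyl_contains(*cfg["h3wt_contains"]):
        result = _result(bundle, labels["h3wt"], ["hgg_h3wt_methylation"])
    elif _ihg_gate(bundle, cfg):
        result = subtype_ihg(bundle, rules)
    else:
        result = _result(bundle, labels["fallback"], ["hgg_fallback"])

    # TP53 status is folded into the HGG label as a suffix.
    if bundle.tp53 is not None and bundle.tp53.status in ("lost", "activated"):
        result.molecular_subtype = (
            f"{result.molecular_subtype}, TP53 {bundle.tp53.status}"
        )
        result.fired_rules.append(f"tp53_{bundle.tp53.status}")
    return result


# ---------------------------------------------------------------------------
# ATRT
# ---------------------------------------------------------------------------

def subtype_atrt(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["atrt"]
    subclass = bundle.methyl_subclass
    if bundle.methyl_high_conf() and subclass in cfg["subclass_map"]:
        return _result(
            bundle,
            cfg["subclass_map"][subclass],
            [f"atrt_methylation_{subclass.lower()}"],
            notes=f"dkfz score {bundle.methyl_score}",
        )
    return _result(bundle, cfg["fallback"], ["atrt_low_confidence_or_absent"])


# ---------------------------------------------------------------------------
# Neuroblastoma
# ---------------------------------------------------------------------------

def subtype_nbl(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["nbl"]
    labels = cfg["labels"]
    diagnosis = bundle.specimen.pathology_diagnosis.lower()
    if not any(g in diagnosis for g in cfg["pathology_gate"]):
        return _result(bundle, None, ["nbl_pathology_gate_failed"])

    dna_available = bool(bundle.gene_status)
    mycn_amp = bundle.gene_cn("MYCN") == "amplification"
    free_text = bundle.specimen.pathology_free_text_diagnosis.lower()
    says_amp = "non-amplified" not in free_text and "amplified" in free_text
    says_non_amp = "non-amplified" in free_text
    tpm = bundle.mycn_tpm
    cutoff = bundle.thresholds.mycn_tpm_cutoff

    if dna_available and mycn_amp:
        review = says_non_amp
        return _result(bundle, labels["amplified"], ["nbl_mycn_cn_amplified"], review=review)
    if dna_available and says_amp:
        # free text conflicts with genetics: the TPM cutoff decides
        if tpm is not None:
            label = labels["amplified"] if tpm >= cutoff else labels["non_amplified"]
            return _result(bundle, label, ["nbl_free_text_conflict_tpm"], review=True)
        return _result(bundle, labels["fallback"], ["nbl_conflict_no_rna"], review=True)
    if dna_available:
        return _result(bundle, labels["non_amplified"], ["nbl_mycn_cn_non_amplified"])
    if tpm is not None:
        label = labels["amplified"] if tpm >= cutoff else labels["non_amplified"]
        return _result(bundle, label, ["nbl_tpm_cutoff"])
    return _result(bundle, labels["fallback"], ["nbl_no_dna_no_rna"])


# ---------------------------------------------------------------------------
# Craniopharyngioma
# ---------------------------------------------------------------------------

def subtype_cranio(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["cranio"]
    labels = cfg["labels"]
    if bundle.methyl_high_conf() and cfg["pap_contains"] in bundle.methyl_subclass:
        return _result(bundle, labels["pap"], ["cranio_pap_methylation"])
    if bundle.methyl_high_conf() and cfg["adam_contains"] in bundle.methyl_subclass:
        return _result(bundle, labels["adam"], ["cranio_adam_methylation"])
    if bundle.prior_subtype:
        return _result(bundle, bundle.prior_subtype, ["cranio_prior_molecular_criteria"])
    return _result(bundle, labels["fallback"], ["cranio_fallback"])


# ---------------------------------------------------------------------------
# Ependymoma
# ---------------------------------------------------------------------------

def subtype_epn(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["epn"]
    labels = cfg["labels"]
    hgg_cfg = rules["hgg"]

    spinal = bundle.location_contains("spinal")
    posterior_fossa = bundle.location_contains("posterior fossa")

    if (spinal and bundle.gene_cn("MYCN") == "amplification") or bundle.methyl_is(
        "EPN, SP-MYCN"
    ):
        return _result(bundle, labels["sp_mycn"], ["epn_sp_mycn"])
    if bundle.has_fusion_pair(cfg["yap1_pairs"]) or bundle.methyl_is("EPN, ST YAP1"):
        return _result(bundle, labels["st_yap1"], ["epn_st_yap1"])
    if bundle.has_fusion_pair(cfg["zfta_pairs"]) or bundle.methyl_is("EPN, ST ZFTA"):
        return _result(bundle, labels["st_zfta"], ["epn_st_zfta"])
    if (
        (bundle.has_arm_event("1q", "gain") and bundle.over_expressed("TKTL1"))
        or bundle.over_expressed("EZHIP")
        or (
            posterior_fossa
            and bundle.has_mutation(
                hgg_cfg["histone_genes"], protein_changes=hgg_cfg["k28_changes"]
            )
        )
        or bundle.methyl_is("EPN, PF A")
    ):
        return _result(bundle, labels["pf_a"], ["epn_pf_a"])
    if (
        (
            (bundle.has_arm_event("6p", "loss") or bundle.has_arm_event("6q", "loss"))
            and (bundle.over_expressed("GPBP1") or bundle.over_expressed("IFT46"))
        )
        or bundle.methyl_is("EPN, PF B")
    ):
        return _result(bundle, labels["pf_b"], ["epn_pf_b"])
    if bundle.methyl_is("EPN, MPE"):
        return _result(bundle, labels["mpe"], ["epn_mpe"])
    if bundle.methyl_is("EPN, PF SE"):
        return _result(bundle, labels["pf_se"], ["epn_pf_se"])
    if bundle.methyl_is("EPN, SP SE"):
        return _result(bundle, labels["sp_se"], ["epn_sp_se"])
    if bundle.methyl_is("EPN, SP"):
        return _result(bundle, labels["sp"], ["epn_sp"])
    return _result(bundle, labels["fallback"], ["epn_fallback"])


# ---------------------------------------------------------------------------
# Low-grade glioma
# ---------------------------------------------------------------------------

def subtype_lgg(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["lgg"]
    subclass = bundle.methyl_subclass
    if bundle.methyl_high_conf() and subclass in cfg["subclass_map"]:
        return _result(
            bundle,
            cfg["subclass_map"][subclass],
            [f"lgg_methylation_{subclass.lower().replace(' ', '_').replace(',', '')}"],
        )
    if bundle.prior_subtype:
        return _result(bundle, bundle.prior_subtype, ["lgg_prior_molecular_criteria"])
    return _result(bundle, cfg["fallback"], ["lgg_fallback"])


# ---------------------------------------------------------------------------
# Medulloblastoma
# ---------------------------------------------------------------------------

def _mb_methyl_group(bundle: EvidenceBundle, cfg: Dict[str, Any]) -> Optional[str]:
    if not bundle.methyl_high_conf():
        return None
    subclass = bundle.methyl_subclass
    if "MB_SHH" in subclass:
        return "SHH"
    if subclass in cfg["group3_classes"]:
        return "Group3"
    if subclass in cfg["group4_classes"]:
        return "Group4"
    if subclass == "MB_WNT":
        return "WNT"
    if subclass == "MB_MYO":
        return "MYO"
    return None


def _mb_shh_age_matches(bundle: EvidenceBundle, cfg: Dict[str, Any]) -> List[Tuple[str, int]]:
    """Age-gated SHH subgroup matches as (subgroup, n_criteria_bullets).

    The bullet count is the specificity used for tie-breaking: a subgroup
    defined by fewer alternative criteria is the more specific claim.
    """
    thr = bundle.thresholds
    age = bundle.age
    matches: List[Tuple[str, int]] = []
    if age is None:
        return matches

    amp_genes = cfg["alpha_amp_genes"]
    if age >= thr.mb_age_alpha and (
        any(
            bundle.gene_cn(g) == "amplification" or bundle.over_expressed(g)
            for g in amp_genes
        )
        or bundle.has_germline_flag("ELP1", "TP53_LFS", "TP53")
        or bundle.has_mutation(["TP53"], hotspot=True)
        or bundle.has_arm_event("9p", "gain")
        or bundle.has_arm_event("17p", "loss")
    ):
        matches.append(("alpha", 4))
    if age < thr.mb_age_beta_gamma and (
        bundle.has_mutation(["KMT2D"], classes=LOF_CLASSES)
        or bundle.gene_cn_in("PTEN", ["loss", "deep deletion"])
        or bundle.under_expressed("PTEN")
        or bundle.has_arm_event("2p", "gain")
        or bundle.has_arm_event("2q", "gain")
    ):
        matches.append(("beta", 3))
    if age < thr.mb_age_beta_gamma and bundle.has_arm_event("2p", "gain"):
        matches.append(("gamma", 1))
    if age >= thr.mb_age_delta and (
        bundle.has_mutation(cfg["delta_lof_genes"], classes=LOF_CLASSES)
        or bundle.has_mutation(cfg["delta_hotspot_genes"], hotspot=True)
        or bundle.has_arm_event("14q", "loss")
    ):
        matches.append(("delta", 3))
    return matches


_SHH_ORDER = {"alpha": 0, "beta": 1, "gamma": 2, "delta": 3}


def subtype_mb_shh(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["mb"]
    sub_labels = cfg["labels"]["shh_subgroups"]
    subclass = bundle.methyl_subclass
    if bundle.methyl_high_conf() and subclass in cfg["shh_subclass_map"]:
        subgroup = cfg["shh_subclass_map"][subclass]
        return _result(
            bundle, sub_labels[subgroup], [f"mb_shh_methylation_{subgroup}"]
        )
    matches = _mb_shh_age_matches(bundle, cfg)
    if matches:
        subgroup = min(matches, key=lambda m: (m[1], _SHH_ORDER[m[0]]))[0]
        return _result(bundle, sub_labels[subgroup], [f"mb_shh_molecular_{subgroup}"])
    return _result(bundle, cfg["labels"]["SHH"], ["mb_shh_unrefined"])


def subtype_mb(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["mb"]
    labels = cfg["labels"]
    group = _mb_methyl_group(bundle, cfg)
    review = False
    fired = []
    if group is not None:
        fired.append(f"mb_methylation_{group.lower()}")
        if bundle.rna_mb_label and bundle.rna_mb_label != group:
            review = True  # methylation wins; disagreement flagged for review
    elif bundle.rna_mb_label:
        group = bundle.rna_mb_label
        fired.append(f"mb_rna_classifier_{group.lower()}")
    if group is None:
        return _result(bundle, labels["fallback"], ["mb_no_classifier"])
    if group == "SHH":
        result = subtype_mb_shh(bundle, rules)
        result.fired_rules = fired + result.fired_rules
        result.review_flag = review or result.review_flag
        return result
    return _result(bundle, labels[group], fired, review=review)


# ---------------------------------------------------------------------------
# Pineoblastoma
# ---------------------------------------------------------------------------

def subtype_pb(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["pb"]
    subclass = bundle.methyl_subclass
    if bundle.methyl_high_conf() and subclass in cfg["subclass_map"]:
        return _result(
            bundle, cfg["subclass_map"][subclass], [f"pb_methylation_{subclass.lower()}"]
        )
    return _result(bundle, cfg["fallback"], ["pb_fallback"])


# ---------------------------------------------------------------------------
# Non-MB, non-ATRT embryonal tumors (ETMR)
# ---------------------------------------------------------------------------

def subtype_etmr(bundle: EvidenceBundle, rules: Dict[str, Any] = DEFAULT_RULES) -> SubtypeResult:
    cfg = rules["etmr"]
    labels = cfg["labels"]
    ttyh1 = bundle.has_fusion_partner(["TTYH1"])
    chr19_amp = bundle.has_arm_event("19p", "gain") or bundle.has_arm_event("19q", "gain")
    if bundle.methyl_is("ETMR_C19MC") or (
        ttyh1 and (chr19_amp or bundle.over_expressed("LIN28A"))
    ):
        return _result(bundle, labels["c19mc"], ["etmr_c19mc"])
    if bundle.over_expressed("LIN28A") and not ttyh1:
        return _result(bundle, labels["nos"], ["etmr_nos"])
    return _result(bundle, labels["fallback"], ["etmr_fallback"])
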