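"""Declarative configuration for the subtyping rule sets.

Label strings, methylation-class maps, marker-gene lists and numeric gates
live here as data so they can be corrected without touching rule logic.
``load_rules`` deep-merges a user YAML file over the defaults.
"""

from __future__ import annotations

import copy
from typing import Any, Dict

import yaml

DEFAULT_RULES: Dict[str, Any] = {
    "hgg": {
        "histone_genes": ["H3F3A", "HIST1H3B", "HIST1H3C", "HIST2H3C"],
        "k28_changes": ["p.K28M", "p.K28I"],
        "dmg_methyl_contains": ["DMG_K27"],
        "oligo_idh_classes": ["O_IDH"],
        "oligosarcoma_classes": ["OLIGOSARC_IDH"],
        "pxa_free_text": ["pleomorphic xanthoastrocytoma", "pxa"],
        "dhg_classes": ["DHG_G34", "GBM_G34"],
        "hgg_idh_classes": ["A_IDH_HG", "GBM_IDH"],
        "h3wt_contains": ["GBM_MES", "GBM_RTK", "HGG_", "HGAP", "AAP", "ped_"],
        "ihg_free_text": ["infant type hemispheric glioma"],
        "rtk_partners": {
            "ALK": ["ALK"],
            "NTRK": ["NTRK1", "NTRK2", "NTRK3"],
            "ROS1": ["ROS1"],
            "MET": ["MET"],
        },
        "labels": {
            "dmg": "DMG, H3 K28",
            "oligo_idh": "Oligo, IDH-mutant",
            "oligosarcoma": "Oligosarcoma, IDH-mutant",
            "pxa": "PXA",
            "dhg": "DHG, H3 G35",
            "hgg_idh": "HGG, IDH",
            "h3wt": "HGG, H3 wild type",
            "ihg_prefix": "IHG",
            "fallback": "HGG, To be classified",
        },
    },
    "atrt": {
        "subclass_map": {
            "ATRT_MYC": "ATRT, MYC",
            "ATRT_SHH": "ATRT, SHH",
            "ATRT_TYR": "ATRT, TYR",
        },
        "fallback": "ATRT, To be classified",
    },
    "nbl": {
        "pathology_gate": ["neuroblastoma", "ganglioneuroblastoma", "ganglioneuroma"],
        "labels": {
            "amplified": "NBL, MYCN amplified",
            "non_amplified": "NBL, MYCN non-amplified",
            "fallback": "NBL, To be classified",
        },
    },
    "cranio": {
        "pap_contains": "CPH_PAP",
        "adam_contains": "CPH_ADM",
        "labels": {
            "pap": "CRANIO, PAP",
            "adam": "CRANIO, ADAM",
            "fallback": "CRANIO, To be classified",
        },
    },
    "epn": {
        "yap1_pairs": [["YAP1", "MAMLD1"], ["YAP1", "MAML2"], ["YAP1", "FAM118B"]],
        "zfta_pairs": [["ZFTA", "RELA"], ["ZFTA", "MAML2"]],
        "labels": {
            "sp_mycn": "EPN, SP-MYCN",
            "st_yap1": "EPN, ST YAP1",
            "st_zfta": "EPN, ST ZFTA",
            "pf_a": "EPN, PF A",
            "pf_b": "EPN, PF B",
            "mpe": "EPN, MPE",
            "pf_se": "EPN, PF SE",
            "sp_se": "EPN, SP SE",
            "sp": "EPN, SP",
            "fallback": "EPN, To be classified",
        },
    },
    "lgg": {
        "subclass_map": {
            "PA_MID": "LGG, other MAPK-altered",
            "PLNTY": "LGG, other MAPK-altered",
            "PA_INF_FGFR": "LGG, FGFR-altered",
            "A_IDH_LG": "LGG, IDH-altered",
            "AG_MYB": "LGG, MYB/MYBL1 fusion",
            "LGG_MYB": "LGG, MYB/MYBL1 fusion",
            "LGG, MAPK": "LGG, MAPK-altered",
            "LGG, BRAF/MAPK": "LGG, BRAF- and MAPK-altered",
            "SEGA, To be classified": "SEGA, To be classified",
        },
        "fallback": "LGG, To be classified",
    },
    "mb": {
        "group3_classes": ["MB_G34_I", "MB_G34_II", "MB_G34_III", "MB_G34_IV"],
        "group4_classes": ["MB_G34_V", "MB_G34_VI", "MB_G34_VII", "MB_G34_VIII"],
        "shh_subclass_map": {
            "MB_SHH_3": "alpha",
            "MB_SHH_1": "beta",
            "MB_SHH_2": "gamma",
            "MB_SHH_4": "delta",
        },
        "alpha_amp_genes": ["MYCN", "GLI2", "CCND2"],
        "delta_lof_genes": ["DDX3X", "SMO"],
        "delta_hotspot_genes": ["TERT", "RNU1-1"],
        "labels": {
            "WNT": "MB, WNT",
            "SHH": "MB, SHH",
            "Group3": "MB, Group3",
            "Group4": "MB, Group4",
            "MYO": "MB, MYO",
            "fallback": "MB, To be classified",
            "shh_subgroups": {
                "alpha": "MB, SHH alpha",
                "beta": "MB, SHH beta",
                "gamma": "MB, SHH gamma",
                "delta": "MB, SHH delta",
            },
        },
    },
    "pb": {
        "subclass_map": {
            "PB_FOXR2": "Pineoblastoma, MYC/FOXR2-activated",
            "PB_RB1": "Pineoblastoma, RB1-altered",
            "PB_GRP1A": "Pineoblastoma, group 1",
            "PB_GRP1B": "Pineoblastoma, group 1",
            "PB_GRP2": "Pineoblastoma, group 2",
        },
        "fallback": "PB, To be classified",
    },
    "etmr": {
        "labels": {
            "c19mc": "ETMR, C19MC-altered",
            "nos": "ETMR, NOS",
            "fallback": "ETMR, To be classified",
        },
    },
    "dispatch": {
        "hgg": [
            "high-grade glioma",
            "glioblastoma",
            "diffuse midline glioma",
            "infant type hemispheric",
            "oligodendroglioma",
        ],
        "atrt": ["atypical teratoid"],
        "nbl": ["neuroblastoma", "ganglioneuroblastoma", "ganglioneuroma"],
        "cranio": ["craniopharyngioma"],
        "epn": ["ependymoma"],
        "lgg": ["low-grade glioma", "pilocytic astrocytoma", "subependymal giant cell"],
        "mb": ["medulloblastoma"],
        "pb": ["pineoblastoma"],
        "etmr": ["embryonal tumor", "multilayered rosettes", "etmr"],
    },
}


def _deep_merge(base: Dict, override: Dict) -> Dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_rules(path=None) -> Dict[str, Any]:
    """Default rule config, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_RULES)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return _deep_merge(DEFAULT_RULES, override)
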