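"""Seeded synthetic cohorts with injected, labeled ground truth.

The generator emulates every input the pipeline consumes — per-caller
MAFs and SEG files, surveyed-region / coding / blacklist BEDs, fusion and
methylation tables, an expression matrix, and a clinical histologies
table — on a toy genome of seven 10-Mb chromosomes. Each tumor event
carries exactly one subtype-defining lesion (mutation, CNV, arm event,
fusion, expression flag, or methylation call) whose expected label is
recorded in a truth table.

All truth values are computed by naive brute force inside this module
(set tallies over the emitted caller assignments, per-bp numpy masks for
region sizes), never by the consensus/TMB code under test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .fusion import PrioritizedFusion
from .intervals import GenomicInterval
from .model import (
    ConsensusVariant,
    CnvSegment,
    FusionCall,
    MethylPrediction,
    SpecimenRecord,
    Thresholds,
    VariantRecord,
)
from .subtypes.evidence import EvidenceBundle
from .tp53 import SomaticTp53Variant, Tp53Evidence, classify_tp53

# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

CHROM_LEN = 10_000_000
CHROMS = ("chr1", "chr2", "chr6", "chr9", "chr14", "chr17", "chr19")

#: Arm layout: p = [0, 4.5 Mb), centromere gap, q = [5 Mb, 10 Mb).
P_ARM = (0, 4_500_000)
Q_ARM = (5_000_000, CHROM_LEN)

#: Marker genes live in the distal q-arm "gene zone" so that arm-level
#: event segments (which cover the proximal 60% of an arm) never touch them.
GENE_ZONE_START = 8_500_000
GENE_STRIDE = 50_000
GENE_LEN = 20_000

MARKER_GENES = (
    "H3F3A", "HIST1H3B", "HIST1H3C", "HIST2H3C", "TP53", "BRAF", "CDKN2A",
    "CDKN2B", "MYCN", "GLI2", "CCND2", "KMT2D", "PTEN", "DDX3X", "SMO",
    "TERT", "RNU1-1", "TKTL1", "EZHIP", "GPBP1", "IFT46", "LIN28A", "TTYH1",
    "ALK", "NTRK1", "NTRK2", "NTRK3", "ROS1", "MET", "YAP1", "MAMLD1",
    "ZFTA", "RELA", "MAML2", "FAM118B", "MYB",
)

EXPR_MARKERS = ("TKTL1", "EZHIP", "GPBP1", "IFT46", "LIN28A", "MYCN",
                "GLI2", "CCND2", "PTEN")
EXPR_BASELINE = 3.0
EXPR_OVER_VALUE = 300.0


def toy_arm_table() -> Dict[str, GenomicInterval]:
    arms = {}
    for chrom in CHROMS:
        short = chrom[3:]
        arms[f"{short}p"] = GenomicInterval(chrom, *P_ARM)
        arms[f"{short}q"] = GenomicInterval(chrom, *Q_ARM)
    return arms


def toy_gene_model() -> Dict[str, GenomicInterval]:
    """Round-robin allocation of marker genes to per-chromosome gene zones."""
    genes = {}
    slots = {chrom: 0 for chrom in CHROMS}
    for i, gene in enumerate(MARKER_GENES):
        chrom = CHROMS[i % len(CHROMS)]
        start = GENE_ZONE_START + slots[chrom] * GENE_STRIDE
        slots[chrom] += 1
        genes[gene] = GenomicInterval(chrom, start, start + GENE_LEN)
    return genes


GENE_MODEL = toy_gene_model()
ARM_TABLE = toy_arm_table()


def _arm_segment(arm: str) -> GenomicInterval:
    """A segment covering 60% of the arm, clear of the gene zone."""
    iv = ARM_TABLE[arm]
    if arm.endswith("p"):
        return GenomicInterval(iv.chrom, 0, 2_700_000)
    return GenomicInterval(iv.chrom, Q_ARM[0], Q_ARM[0] + 3_000_000)


STATUS_TO_CN = {"amplification": 8, "gain": 3, "neutral": 2, "loss": 1,
                "deep deletion": 0}


# ---------------------------------------------------------------------------
# Random consensus-SNV cohort (oracle fixture)
# ---------------------------------------------------------------------------

@dataclass
class SnvOracleCohort:
    """Per-caller variant lists plus a brute-force expected consensus."""

    per_caller: Dict[str, List[VariantRecord]]
    expected_keys: Set[tuple]


def random_snv_cohort(
    seed: int,
    n_variants: int = 4000,
    hotspot_rate: float = 0.10,
    shared_rate: float = 0.20,
    sample_id: str = "BS_RAND",
    callers: Sequence[str] = ("strelka2", "mutect2", "lancet", "vardict"),
) -> SnvOracleCohort:
    """Random SNP pool with caller subsets; truth by naive support tally."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    per_caller: Dict[str, List[VariantRecord]] = {c: [] for c in callers}
    support: Dict[tuple, Set[str]] = {}
    hotspots: Set[tuple] = set()
    used = set()
    for _ in range(n_variants):
        while True:
            chrom = CHROMS[rng.integers(len(CHROMS))]
            pos = int(rng.integers(1, CHROM_LEN))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        if rng.random() < shared_rate:
            k = 2 + int(rng.integers(len(callers) - 1))
            chosen = list(rng.choice(len(callers), size=k, replace=False))
        else:
            chosen = [int(rng.integers(len(callers)))]
        hotspot = rng.random() < hotspot_rate
        rec_callers = {callers[i] for i in chosen}
        key = (sample_id, chrom, pos, pos, ref, alt)
        support[key] = rec_callers
        if hotspot:
            hotspots.add(key)
        for caller in rec_callers:
            per_caller[caller].append(
                VariantRecord(
                    sample_id=sample_id, chrom=chrom, start=pos, end=pos,
                    ref=ref, alt=alt, variant_class="Missense_Mutation",
                    variant_type="SNP", gene="RANDGENE",
                    callers=frozenset({caller}), t_depth=100, alt_depth=30,
                    hotspot=hotspot,
                )
            )
    expected = {
        key for key, callers_ in support.items()
        if len(callers_) >= 2 or key in hotspots
    }
    return SnvOracleCohort(per_caller=per_caller, expected_keys=expected)


# ---------------------------------------------------------------------------
# Random CNV cohort (oracle fixture)
# ---------------------------------------------------------------------------

def random_cnv_cohort(
    seed: int,
    n_samples: int = 20,
    segments_per_caller: int = 200,
    callers: Sequence[str] = ("controlfreec", "cnvkit", "gatk"),
) -> Dict[str, List[CnvSegment]]:
    """Random non-neutral segments for the pairwise-consensus brute force."""
    rng = np.random.default_rng(seed)
    statuses = ["gain", "loss", "amplification", "deep deletion"]
    per_caller: Dict[str, List[CnvSegment]] = {c: [] for c in callers}
    for caller in callers:
        for _ in range(segments_per_caller):
            sample = f"BS_{rng.integers(n_samples):04d}"
            chrom = CHROMS[rng.integers(len(CHROMS))]
            # confined to the proximal 2 Mb so caller segments overlap often
            start = int(rng.integers(0, 2_000_000))
            length = int(rng.integers(1_000, 200_000))
            status = statuses[rng.integers(4)]
            per_caller[caller].append(
                CnvSegment(
                    sample_id=sample,
                    interval=GenomicInterval(chrom, start, start + length),
                    caller=caller,
                    copy_number=STATUS_TO_CN[status],
                    status=status,
                )
            )
    return per_caller


# ---------------------------------------------------------------------------
# Subtype cohort plan
# ---------------------------------------------------------------------------

@dataclass
class EventPlan:
    """One planned tumor event with its injected lesion and expected label."""

    event_id: str
    pathology_diagnosis: str
    expected_subtype: Optional[str]
    methyl: Optional[Tuple[str, float]] = None
    methyl_gated: bool = False  # does the expected label rely on the score gate?
    variants: List[dict] = field(default_factory=list)
    gene_cn: Dict[str, str] = field(default_factory=dict)
    arm_events: List[Tuple[str, str]] = field(default_factory=list)
    fusions: List[Tuple[str, str]] = field(default_factory=list)
    expr_over: List[str] = field(default_factory=list)
    expr_under: List[str] = field(default_factory=list)
    mycn_tpm: Optional[float] = None
    free_text: str = ""
    age: Optional[float] = None
    location: str = ""
    germline: List[str] = field(default_factory=list)
    cancer_group: str = ""
    rna_mb_label: str = ""
    prior_subtype: str = ""
    has_dna: bool = True
    has_rna: bool = True
    sample_id: str = ""


def _v(gene, protein="", vclass="Missense_Mutation", hotspot=False):
    return {"gene": gene, "protein_change": protein, "variant_class": vclass,
            "hotspot": hotspot}


def build_event_plans() -> List[EventPlan]:
    """The rule-covering cohort: >= 1 event per rule in every histology."""
    E = EventPlan
    hgg, epn, mb = "High-grade glioma", "Ependymoma", "Medulloblastoma"
    plans = [
        # --- HGG ---
        E("hgg_dmg_mutation", hgg, "DMG, H3 K28",
          variants=[_v("H3F3A", "p.K28M")]),
        E("hgg_dmg_methyl", hgg, "DMG, H3 K28", methyl=("DMG_K27", 0.9),
          methyl_gated=True),
        E("hgg_oligo_idh", hgg, "Oligo, IDH-mutant", methyl=("O_IDH", 0.85),
          methyl_gated=True),
        E("hgg_oligosarc", hgg, "Oligosarcoma, IDH-mutant",
          methyl=("OLIGOSARC_IDH", 0.85), methyl_gated=True),
        E("hgg_pxa", hgg, "PXA", free_text="pleomorphic xanthoastrocytoma",
          variants=[_v("BRAF", "p.V600E")],
          gene_cn={"CDKN2A": "deep deletion"}),
        E("hgg_dhg", hgg, "DHG, H3 G35", methyl=("DHG_G34", 0.9),
          methyl_gated=True),
        E("hgg_idh", hgg, "HGG, IDH", methyl=("GBM_IDH", 0.9),
          methyl_gated=True),
        E("hgg_h3wt", hgg, "HGG, H3 wild type", methyl=("GBM_MES_TYP", 0.9),
          methyl_gated=True),
        E("ihg_alk", hgg, "IHG, ALK-altered", methyl=("IHG", 0.9),
          fusions=[("ALK", "EML4")]),
        E("ihg_ntrk", hgg, "IHG, NTRK-altered",
          free_text="infant type hemispheric glioma",
          fusions=[("ETV6", "NTRK2")]),
        E("ihg_ros1", hgg, "IHG, ROS1-altered", methyl=("IHG", 0.9),
          fusions=[("GOPC", "ROS1")]),
        E("ihg_met", hgg, "IHG, MET-altered",
          free_text="infant type hemispheric glioma",
          fusions=[("TFG", "MET")]),
        E("ihg_tbc", hgg, "IHG, To be classified", methyl=("IHG", 0.9)),
        E("hgg_fallback", hgg, "HGG, To be classified"),
        E("hgg_tp53_lost", hgg, "DMG, H3 K28, TP53 lost",
          variants=[_v("H3F3A", "p.K28M"), _v("TP53", "p.R175H")]),
        E("hgg_tp53_activated", hgg, "DMG, H3 K28, TP53 activated",
          variants=[_v("H3F3A", "p.K28M"),
                    _v("TP53", "p.R273C", hotspot=True)]),
        # --- ATRT ---
        E("atrt_myc", "Atypical Teratoid Rhabdoid Tumor", "ATRT, MYC",
          methyl=("ATRT_MYC", 0.9), methyl_gated=True),
        E("atrt_shh", "Atypical Teratoid Rhabdoid Tumor", "ATRT, SHH",
          methyl=("ATRT_SHH", 0.85), methyl_gated=True),
        E("atrt_tyr", "Atypical Teratoid Rhabdoid Tumor", "ATRT, TYR",
          methyl=("ATRT_TYR", 0.95), methyl_gated=True),
        E("atrt_lowconf", "Atypical Teratoid Rhabdoid Tumor",
          "ATRT, To be classified", methyl=("ATRT_MYC", 0.79)),
        E("atrt_none", "Atypical Teratoid Rhabdoid Tumor",
          "ATRT, To be classified"),
        # --- NBL ---
        E("nbl_cn_amp", "Neuroblastoma", "NBL, MYCN amplified",
          gene_cn={"MYCN": "amplification"}),
        E("nbl_cn_nonamp", "Neuroblastoma", "NBL, MYCN non-amplified"),
        E("nbl_conflict_tpm", "Ganglioneuroblastoma", "NBL, MYCN amplified",
          free_text="NBL, MYCN amplified", mycn_tpm=300.0),
        E("nbl_tpm_boundary", "Neuroblastoma", "NBL, MYCN amplified",
          has_dna=False, mycn_tpm=140.83),
        E("nbl_tpm_low", "Ganglioneuroma", "NBL, MYCN non-amplified",
          has_dna=False, mycn_tpm=20.0),
        E("nbl_tbc", "Neuroblastoma", "NBL, To be classified",
          has_dna=False, has_rna=False),
        # --- CRANIO ---
        E("cranio_pap", "Craniopharyngioma", "CRANIO, PAP",
          methyl=("CNS_CPH_PAP", 0.9), methyl_gated=True),
        E("cranio_adam", "Craniopharyngioma", "CRANIO, ADAM",
          methyl=("CNS_CPH_ADM", 0.9), methyl_gated=True),
        E("cranio_lowconf", "Craniopharyngioma", "CRANIO, To be classified",
          methyl=("CNS_CPH_PAP", 0.5)),
        E("cranio_prior", "Craniopharyngioma", "CRANIO, ADAM",
          prior_subtype="CRANIO, ADAM"),
        # --- EPN ---
        E("epn_sp_mycn_anat", epn, "EPN, SP-MYCN", location="spinal cord",
          gene_cn={"MYCN": "amplification"}),
        E("epn_sp_mycn_methyl", epn, "EPN, SP-MYCN",
          methyl=("EPN, SP-MYCN", 0.9), methyl_gated=True),
        E("epn_yap1", epn, "EPN, ST YAP1", fusions=[("YAP1", "MAMLD1")]),
        E("epn_zfta", epn, "EPN, ST ZFTA", fusions=[("ZFTA", "RELA")]),
        E("epn_pf_a_1q", epn, "EPN, PF A", arm_events=[("1q", "gain")],
          expr_over=["TKTL1"]),
        E("epn_pf_a_ezhip", epn, "EPN, PF A", expr_over=["EZHIP"]),
        E("epn_pf_a_h3", epn, "EPN, PF A", location="posterior fossa",
          variants=[_v("HIST1H3B", "p.K28M")]),
        E("epn_pf_a_methyl", epn, "EPN, PF A", methyl=("EPN, PF A", 0.9),
          methyl_gated=True),
        E("epn_pf_b_6q", epn, "EPN, PF B", arm_events=[("6q", "loss")],
          expr_over=["GPBP1"]),
        E("epn_pf_b_methyl", epn, "EPN, PF B", methyl=("EPN, PF B", 0.8),
          methyl_gated=True),
        E("epn_mpe", epn, "EPN, MPE", methyl=("EPN, MPE", 0.9),
          methyl_gated=True),
        E("epn_pf_se", epn, "EPN, PF SE", methyl=("EPN, PF SE", 0.9),
          methyl_gated=True),
        E("epn_sp_se", epn, "EPN, SP SE", methyl=("EPN, SP SE", 0.9),
          methyl_gated=True),
        E("epn_sp", epn, "EPN, SP", methyl=("EPN, SP", 0.9),
          methyl_gated=True),
        E("epn_tbc", epn, "EPN, To be classified"),
        # --- LGG ---
        E("lgg_pa_mid", "Low-grade glioma", "LGG, other MAPK-altered",
          methyl=("PA_MID", 0.9), methyl_gated=True),
        E("lgg_fgfr", "Low-grade glioma", "LGG, FGFR-altered",
          methyl=("PA_INF_FGFR", 0.9), methyl_gated=True),
        E("lgg_idh", "Low-grade glioma", "LGG, IDH-altered",
          methyl=("A_IDH_LG", 0.9), methyl_gated=True),
        E("lgg_myb", "Low-grade glioma", "LGG, MYB/MYBL1 fusion",
          methyl=("LGG_MYB", 0.9), methyl_gated=True),
        E("lgg_mapk", "Low-grade glioma", "LGG, MAPK-altered",
          methyl=("LGG, MAPK", 0.9), methyl_gated=True),
        E("lgg_braf_mapk", "Low-grade glioma", "LGG, BRAF- and MAPK-altered",
          methyl=("LGG, BRAF/MAPK", 0.9), methyl_gated=True),
        E("lgg_sega", "Low-grade glioma", "SEGA, To be classified",
          methyl=("SEGA, To be classified", 0.9), methyl_gated=True),
        E("lgg_prior", "Pilocytic astrocytoma", "LGG, KIAA1549::BRAF",
          prior_subtype="LGG, KIAA1549::BRAF"),
        E("lgg_tbc", "Low-grade glioma", "LGG, To be classified"),
        # --- MB ---
        E("mb_wnt", mb, "MB, WNT", methyl=("MB_WNT", 0.9), methyl_gated=True),
        E("mb_g3", mb, "MB, Group3", methyl=("MB_G34_II", 0.9),
          methyl_gated=True),
        E("mb_g4", mb, "MB, Group4", methyl=("MB_G34_VII", 0.9),
          methyl_gated=True),
        E("mb_myo", mb, "MB, MYO", methyl=("MB_MYO", 0.9), methyl_gated=True),
        E("mb_rna_g4", mb, "MB, Group4", rna_mb_label="Group4"),
        E("mb_shh_m3", mb, "MB, SHH alpha", methyl=("MB_SHH_3", 0.9),
          methyl_gated=True),
        E("mb_shh_m1", mb, "MB, SHH beta", methyl=("MB_SHH_1", 0.9),
          methyl_gated=True),
        E("mb_shh_m2", mb, "MB, SHH gamma", methyl=("MB_SHH_2", 0.9),
          methyl_gated=True),
        E("mb_shh_m4", mb, "MB, SHH delta", methyl=("MB_SHH_4", 0.9),
          methyl_gated=True),
        E("mb_shh_alpha_amp", mb, "MB, SHH alpha", rna_mb_label="SHH",
          age=6.0, gene_cn={"GLI2": "amplification"}),
        E("mb_shh_alpha_expr", mb, "MB, SHH alpha", rna_mb_label="SHH",
          age=5.0, expr_over=["CCND2"]),
        E("mb_shh_alpha_germline", mb, "MB, SHH alpha", rna_mb_label="SHH",
          age=3.0, germline=["ELP1"]),
        E("mb_shh_alpha_tp53", mb, "MB, SHH alpha", rna_mb_label="SHH",
          age=4.0, variants=[_v("TP53", "p.R175H", hotspot=True)]),
        E("mb_shh_alpha_17p", mb, "MB, SHH alpha", rna_mb_label="SHH",
          age=2.0, arm_events=[("17p", "loss")]),
        E("mb_shh_beta_kmt2d", mb, "MB, SHH beta", rna_mb_label="SHH",
          age=1.0, variants=[_v("KMT2D", "p.Q100*", "Nonsense_Mutation")]),
        E("mb_shh_beta_pten", mb, "MB, SHH beta", rna_mb_label="SHH",
          age=2.0, gene_cn={"PTEN": "deep deletion"}),
        E("mb_shh_beta_pten_expr", mb, "MB, SHH beta", rna_mb_label="SHH",
          age=1.0, expr_under=["PTEN"]),
        E("mb_shh_beta_2q", mb, "MB, SHH beta", rna_mb_label="SHH",
          age=3.0, arm_events=[("2q", "gain")]),
        E("mb_shh_gamma_2p", mb, "MB, SHH gamma", rna_mb_label="SHH",
          age=3.0, arm_events=[("2p", "gain")]),
        E("mb_shh_delta_ddx3x", mb, "MB, SHH delta", rna_mb_label="SHH",
          age=12.0, variants=[_v("DDX3X", "p.R50fs", "Frame_Shift_Del")]),
        E("mb_shh_delta_tert", mb, "MB, SHH delta", rna_mb_label="SHH",
          age=10.0, variants=[_v("TERT", "p.0", "5'Flank", hotspot=True)]),
        E("mb_shh_delta_14q", mb, "MB, SHH delta", rna_mb_label="SHH",
          age=15.0, arm_events=[("14q", "loss")]),
        E("mb_shh_unrefined", mb, "MB, SHH", rna_mb_label="SHH", age=7.0),
        E("mb_tbc", mb, "MB, To be classified"),
        # --- PB ---
        E("pb_foxr2", "Pineoblastoma", "Pineoblastoma, MYC/FOXR2-activated",
          methyl=("PB_FOXR2", 0.9), methyl_gated=True),
        E("pb_rb1", "Pineoblastoma", "Pineoblastoma, RB1-altered",
          methyl=("PB_RB1", 0.9), methyl_gated=True),
        E("pb_grp1a", "Pineoblastoma", "Pineoblastoma, group 1",
          methyl=("PB_GRP1A", 0.9), methyl_gated=True),
        E("pb_grp1b", "Pineoblastoma", "Pineoblastoma, group 1",
          methyl=("PB_GRP1B", 0.85), methyl_gated=True),
        E("pb_grp2", "Pineoblastoma", "Pineoblastoma, group 2",
          methyl=("PB_GRP2", 0.9), methyl_gated=True),
        E("pb_lowconf", "Pineoblastoma", "PB, To be classified",
          methyl=("PB_RB1", 0.7)),
        # --- ETMR ---
        E("etmr_methyl", "Embryonal tumor with multilayered rosettes",
          "ETMR, C19MC-altered", methyl=("ETMR_C19MC", 0.9),
          methyl_gated=True),
        E("etmr_ttyh1_chr19", "Embryonal tumor with multilayered rosettes",
          "ETMR, C19MC-altered", fusions=[("TTYH1", "LHX1")],
          arm_events=[("19q", "gain")]),
        E("etmr_ttyh1_lin28a", "Embryonal tumor with multilayered rosettes",
          "ETMR, C19MC-altered", fusions=[("TTYH1", "LHX1")],
          expr_over=["LIN28A"]),
        E("etmr_nos", "Embryonal tumor with multilayered rosettes",
          "ETMR, NOS", expr_over=["LIN28A"]),
        E("etmr_tbc", "Embryonal tumor with multilayered rosettes",
          "ETMR, To be classified"),
        # --- outside covered histologies ---
        E("other_histology", "Meningioma", None),
    ]
    for i, plan in enumerate(plans):
        plan.sample_id = f"BS_{i + 1:04d}"
        if not plan.cancer_group:
            plan.cancer_group = plan.pathology_diagnosis
    return plans


# ---------------------------------------------------------------------------
# In-memory bundles (fast path used by tests)
# ---------------------------------------------------------------------------

def _plan_specimen(plan: EventPlan, i: int) -> SpecimenRecord:
    return SpecimenRecord(
        sample_id=plan.sample_id,
        participant_id=f"PT_{i + 1:04d}",
        tumor_event_id=plan.event_id,
        experimental_strategy="WGS" if plan.has_dna else "RNA-Seq",
        tumor_descriptor="Initial CNS Tumor",
        pathology_diagnosis=plan.pathology_diagnosis,
        pathology_free_text_diagnosis=plan.free_text,
        age_at_diagnosis_years=plan.age,
        germline_flags=frozenset(plan.germline),
        anatomical_site=plan.location,
        cancer_group=plan.cancer_group,
    )


def plan_to_bundle(plan: EventPlan, i: int = 0,
                   thresholds: Thresholds = Thresholds()) -> EvidenceBundle:
    """Build the evidence bundle a correct pipeline would assemble."""
    specimen = _plan_specimen(plan, i)
    variants = []
    for v in plan.variants:
        gene_iv = GENE_MODEL[v["gene"]]
        rec = VariantRecord(
            sample_id=plan.sample_id, chrom=gene_iv.chrom,
            start=gene_iv.start + 101, end=gene_iv.start + 101,
            ref="C", alt="A", variant_class=v["variant_class"],
            variant_type="SNP", gene=v["gene"],
            protein_change=v["protein_change"],
            callers=frozenset({"strelka2", "mutect2"}),
            t_depth=100, alt_depth=40, n_depth=30, hotspot=v["hotspot"],
        )
        variants.append(ConsensusVariant(record=rec,
                                         consensus_reason="multi_caller"))
    gene_status: Dict[str, str] = {}
    if plan.has_dna:
        gene_status = {g: "neutral" for g in GENE_MODEL}
        gene_status.update(plan.gene_cn)
    fusions = [
        PrioritizedFusion(
            FusionCall(plan.sample_id, g5, g3, "arriba", plan.cancer_group),
            putative_oncogenic=True,
            retained_reason=frozenset({"both_callers"}),
        )
        for g5, g3 in plan.fusions
    ]
    methyl = []
    if plan.methyl is not None:
        methyl.append(MethylPrediction(plan.sample_id, "dkfz_v12",
                                       plan.methyl[0], plan.methyl[1]))
    tp53_variants = tuple(
        SomaticTp53Variant(v["protein_change"], v["hotspot"])
        for v in plan.variants if v["gene"] == "TP53"
    )
    tp53 = classify_tp53(
        Tp53Evidence(
            sample_id=plan.sample_id,
            somatic_variants=tp53_variants,
            cnv_loss=plan.gene_cn.get("TP53") in ("loss", "deep deletion"),
        ),
        thresholds,
    )
    mycn_tpm = plan.mycn_tpm
    if mycn_tpm is None and plan.has_rna:
        mycn_tpm = EXPR_BASELINE
    return EvidenceBundle(
        specimen=specimen,
        variants=variants,
        gene_status=gene_status,
        arm_events=set(plan.arm_events),
        fusions=fusions,
        expr_over=set(plan.expr_over),
        expr_under=set(plan.expr_under),
        mycn_tpm=mycn_tpm,
        methyl=methyl,
        tp53=tp53,
        rna_mb_label=plan.rna_mb_label,
        prior_subtype=plan.prior_subtype,
        thresholds=thresholds,
    )


def subtype_cohort(thresholds: Thresholds = Thresholds()):
    """(plans, bundles) for the rule-covering cohort."""
    plans = build_event_plans()
    bundles = [plan_to_bundle(p, i, thresholds) for i, p in enumerate(plans)]
    return plans, bundles


# ---------------------------------------------------------------------------
# On-disk cohort generation
# ---------------------------------------------------------------------------

def _maf_row(sample, chrom, pos, ref, alt, gene="NOISE", vclass="Missense_Mutation",
             vtype="SNP", protein="", hotspot=False, t_depth=100, alt_depth=40,
             n_depth=30, gnomad=""):
    return {
        "Hugo_Symbol": gene, "Chromosome": chrom, "Start_Position": pos,
        "End_Position": pos + len(ref) - 1, "Reference_Allele": ref,
        "Tumor_Seq_Allele2": alt, "Variant_Classification": vclass,
        "Variant_Type": vtype, "Tumor_Sample_Barcode": sample,
        "t_depth": t_depth, "t_alt_count": alt_depth, "n_depth": n_depth,
        "HGVSp_Short": protein, "gnomAD_AF": gnomad,
        "HotSpotAllele": "Yes" if hotspot else "",
    }


def _surveyed_regions() -> Dict[str, List[Tuple[str, int, int]]]:
    """Per-caller surveyed areas: whole genome minus a caller-specific hole."""
    holes = {"strelka2": (1_000_000, 1_010_000),
             "mutect2": (2_000_000, 2_015_000),
             "vardict": (3_000_000, 3_005_000)}
    out = {}
    for caller, (h0, h1) in holes.items():
        rows = []
        for chrom in CHROMS:
            rows.append((chrom, 0, h0))
            rows.append((chrom, h1, CHROM_LEN))
        out[caller] = rows
    return out


def _brute_force_masks() -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Per-bp numpy masks for the WGS all-mutation and coding denominators."""
    surveyed = _surveyed_regions()
    all_mask = {c: np.ones(CHROM_LEN, dtype=bool) for c in CHROMS}
    for rows in surveyed.values():
        caller_mask = {c: np.zeros(CHROM_LEN, dtype=bool) for c in CHROMS}
        for chrom, s, e in rows:
            caller_mask[chrom][s:e] = True
        for c in CHROMS:
            all_mask[c] &= caller_mask[c]
    cds_mask = {c: np.zeros(CHROM_LEN, dtype=bool) for c in CHROMS}
    for iv in GENE_MODEL.values():
        cds_mask[iv.chrom][iv.start:iv.end] = True
    coding_mask = {c: all_mask[c] & cds_mask[c] for c in CHROMS}
    return all_mask, coding_mask


@dataclass
class GeneratedCohort:
    """Paths plus brute-force truth for a generated on-disk cohort."""

    directory: Path
    plans: List[EventPlan]
    truth: pd.DataFrame


def generate_cohort(outdir, seed: int = 1,
                    thresholds: Thresholds = Thresholds()) -> GeneratedCohort:
    """Write a complete fixture cohort to ``outdir`` (deterministic per seed).

    The truth table carries, per event: the expected molecular subtype,
    whether that label depends on the methylation confidence gate, the
    expected number of consensus small variants (naive support tally over
    the emitted caller assignments, with the germline-leakage predicate
    re-stated inline), and expected TMB numerators computed against
    per-bp denominator masks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    plans = build_event_plans()

    maf_rows: Dict[str, List[dict]] = {c: [] for c in
                                       ("strelka2", "mutect2", "lancet", "vardict")}
    seg_rows: Dict[str, List[dict]] = {"controlfreec": [], "cnvkit": []}
    fusion_rows: List[dict] = []
    methyl_rows: List[dict] = []
    hist_rows: List[dict] = []
    # naive truth bookkeeping: per sample, {key -> (set of callers, hotspot,
    # class, dropped_by_germline)}
    truth_support: Dict[str, Dict[tuple, dict]] = {}

    def add_variant(sample, chrom, pos, ref, alt, callers, *, gene="NOISE",
                    vclass="Missense_Mutation", vtype="SNP", protein="",
                    hotspot=False, n_depth=30, gnomad=""):
        for caller in callers:
            maf_rows[caller].append(
                _maf_row(sample, chrom, pos, ref, alt, gene=gene, vclass=vclass,
                         vtype=vtype, protein=protein, hotspot=hotspot,
                         n_depth=n_depth, gnomad=gnomad)
            )
        key = (chrom, pos, ref, alt)
        entry = truth_support.setdefault(sample, {}).setdefault(
            key, {"callers": set(), "hotspot": False, "vclass": vclass,
                  "germline_leak": False}
        )
        entry["callers"].update(callers)
        entry["hotspot"] = entry["hotspot"] or hotspot
        # germline-leakage predicate restated: non-hotspot, shallow normal,
        # common in the population
        entry["germline_leak"] = (
            not entry["hotspot"]
            and n_depth is not None and n_depth <= 7
            and gnomad not in ("", None) and float(gnomad) > 0.001
        )

    def add_gene_segment(sample, gene, status):
        iv = GENE_MODEL[gene]
        for caller in seg_rows:
            seg_rows[caller].append({
                "sample_id": sample, "chrom": iv.chrom,
                "start": iv.start - 5_000, "end": iv.end + 5_000,
                "copy_number": STATUS_TO_CN[status], "status": status,
            })

    def add_arm_segment(sample, arm, direction):
        iv = _arm_segment(arm)
        status = "gain" if direction == "gain" else "loss"
        for caller in seg_rows:
            seg_rows[caller].append({
                "sample_id": sample, "chrom": iv.chrom, "start": iv.start,
                "end": iv.end, "copy_number": STATUS_TO_CN[status],
                "status": status,
            })

    expr_samples: List[str] = []
    expr_over_by_gene: Dict[str, List[str]] = {}
    expr_under_by_gene: Dict[str, List[str]] = {}
    mycn_overrides: Dict[str, float] = {}

    for i, plan in enumerate(plans):
        sample = plan.sample_id
        hist_rows.append({
            "sample_id": sample,
            "participant_id": f"PT_{i + 1:04d}",
            "tumor_event_id": plan.event_id,
            "experimental_strategy": "WGS" if plan.has_dna else "RNA-Seq",
            "tumor_descriptor": "Initial CNS Tumor",
            "pathology_diagnosis": plan.pathology_diagnosis,
            "pathology_free_text_diagnosis": plan.free_text,
            "age_at_diagnosis_years": "" if plan.age is None else plan.age,
            "germline_flags": ",".join(plan.germline),
            "anatomical_site": plan.location,
            "cancer_group": plan.cancer_group,
            "rna_mb_label": plan.rna_mb_label,
            "prior_subtype": plan.prior_subtype,
        })
        if plan.methyl is not None:
            methyl_rows.append({
                "sample_id": sample, "classifier": "dkfz_v12",
                "subclass": plan.methyl[0], "score": plan.methyl[1],
            })
        for g5, g3 in plan.fusions:
            for caller in ("arriba", "starfusion"):
                fusion_rows.append({
                    "sample_id": sample, "gene5": g5, "gene3": g3,
                    "caller": caller, "cancer_group": plan.cancer_group,
                    "annotations": "",
                })
        if plan.has_rna:
            expr_samples.append(sample)
            for gene in plan.expr_over:
                expr_over_by_gene.setdefault(gene, []).append(sample)
            for gene in plan.expr_under:
                expr_under_by_gene.setdefault(gene, []).append(sample)
            if plan.mycn_tpm is not None:
                mycn_overrides[sample] = plan.mycn_tpm
        if not plan.has_dna:
            continue

        # injected lesion variants (two high-priority callers)
        for k, v in enumerate(plan.variants):
            iv = GENE_MODEL[v["gene"]]
            add_variant(sample, iv.chrom, iv.start + 101 + 10 * k, "C", "A",
                        ("strelka2", "mutect2"), gene=v["gene"],
                        vclass=v["variant_class"], protein=v["protein_change"],
                        hotspot=v["hotspot"])
        # injected CNV lesions and arm events
        for gene, status in plan.gene_cn.items():
            add_gene_segment(sample, gene, status)
        for arm, direction in plan.arm_events:
            add_arm_segment(sample, arm, direction)
        # every DNA sample registers in the SEG files (neutral backbone)
        for caller in seg_rows:
            seg_rows[caller].append({
                "sample_id": sample, "chrom": "chr1", "start": 5_000_000,
                "end": 5_100_000, "copy_number": 2, "status": "neutral",
            })
        # passenger noise: shared calls survive, private ones do not
        for k in range(4):
            pos = int(rng.integers(6_100_000, 8_400_000))
            vclass = "Missense_Mutation" if k % 2 == 0 else "Silent"
            add_variant(sample, CHROMS[int(rng.integers(len(CHROMS)))], pos,
                        "G", "T", ("strelka2", "mutect2", "lancet"),
                        vclass=vclass)
        for caller in ("lancet", "vardict"):
            pos = int(rng.integers(6_100_000, 8_400_000))
            add_variant(sample, CHROMS[int(rng.integers(len(CHROMS)))], pos,
                        "A", "G", (caller,))
        # germline leakage: shallow normal + common population allele
        for _ in range(2):
            pos = int(rng.integers(6_100_000, 8_400_000))
            add_variant(sample, CHROMS[int(rng.integers(len(CHROMS)))], pos,
                        "T", "C", ("strelka2", "mutect2"), n_depth=5,
                        gnomad="0.01")

    # one constructed MNP case: Strelka2 SNP pair + Mutect2 DNP
    mnp_sample = plans[0].sample_id
    mnp_chrom, mnp_pos = "chr1", 6_000_011
    for pos, ref, alt in ((mnp_pos, "C", "A"), (mnp_pos + 1, "G", "T")):
        maf_rows["strelka2"].append(
            _maf_row(mnp_sample, mnp_chrom, pos, ref, alt, gene="NOISEMNP")
        )
    maf_rows["mutect2"].append(
        _maf_row(mnp_sample, mnp_chrom, mnp_pos, "CG", "AT", gene="NOISEMNP",
                 vtype="DNP")
    )
    # by construction the reconstructed DNP is supported by both callers
    truth_support[mnp_sample][(mnp_chrom, mnp_pos, "CG", "AT")] = {
        "callers": {"strelka2", "mutect2"}, "hotspot": False,
        "vclass": "Missense_Mutation", "germline_leak": False,
    }

    # ---- write caller tables ----
    for caller, rows in maf_rows.items():
        pd.DataFrame(rows).to_csv(outdir / f"{caller}.maf.tsv", sep="\t",
                                  index=False)
    for caller, rows in seg_rows.items():
        pd.DataFrame(
            rows, columns=["sample_id", "chrom", "start", "end",
                           "copy_number", "status"]
        ).to_csv(outdir / f"{caller}.seg.tsv", sep="\t", index=False)
    pd.DataFrame(
        fusion_rows, columns=["sample_id", "gene5", "gene3", "caller",
                              "cancer_group", "annotations"]
    ).to_csv(outdir / "fusions.tsv", sep="\t", index=False)
    pd.DataFrame(
        methyl_rows, columns=["sample_id", "classifier", "subclass", "score"]
    ).to_csv(outdir / "methyl.tsv", sep="\t", index=False)
    pd.DataFrame(hist_rows).to_csv(outdir / "histologies.tsv", sep="\t",
                                   index=False)
    pd.DataFrame(columns=["sample_id", "gene"]).to_csv(
        outdir / "sv.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample_id": s, "score": 0.3} for s in expr_samples]
    ).to_csv(outdir / "tp53_scores.tsv", sep="\t", index=False)

    # ---- BEDs, gene model, arm table ----
    for caller, rows in _surveyed_regions().items():
        with open(outdir / f"surveyed_{caller}.bed", "w") as fh:
            for chrom, s, e in rows:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    with open(outdir / "cds.bed", "w") as fh:
        for gene, iv in sorted(GENE_MODEL.items(), key=lambda kv: kv[1]):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(outdir / "genes.bed", "w") as fh:
        for gene, iv in sorted(GENE_MODEL.items(), key=lambda kv: kv[1]):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\n")
    with open(outdir / "blacklist.bed", "w") as fh:
        fh.write("chr1\t4500000\t5000000\n")
    with open(outdir / "arms.tsv", "w") as fh:
        fh.write("arm\tchrom\tstart\tend\n")
        for arm, iv in sorted(ARM_TABLE.items()):
            fh.write(f"{arm}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")

    # ---- expression matrix ----
    expr_genes = list(EXPR_MARKERS) + [f"FILLER{i}" for i in range(10)]
    rows = []
    for gi, gene in enumerate(expr_genes):
        values = {}
        for sample in expr_samples:
            if sample in expr_over_by_gene.get(gene, []):
                values[sample] = EXPR_OVER_VALUE
            elif sample in expr_under_by_gene.get(gene, []):
                values[sample] = 0.0
            elif gene == "MYCN" and sample in mycn_overrides:
                values[sample] = mycn_overrides[sample]
            else:
                values[sample] = EXPR_BASELINE
        rows.append({"gene_id": f"ENSG{gi:011d}", "gene_symbol": gene, **values})
    # duplicate-symbol pair and an all-zero row exercise the collapse rule
    rows.append({"gene_id": "ENSGDUP00001", "gene_symbol": "DUPGENE",
                 **{s: 5.0 for s in expr_samples}})
    rows.append({"gene_id": "ENSGDUP00002", "gene_symbol": "DUPGENE",
                 **{s: 1.0 for s in expr_samples}})
    rows.append({"gene_id": "ENSGZERO0001", "gene_symbol": "ZEROGENE",
                 **{s: 0.0 for s in expr_samples}})
    pd.DataFrame(rows).to_csv(outdir / "expression.tsv", sep="\t", index=False)

    # ---- brute-force truth ----
    all_mask, coding_mask = _brute_force_masks()
    den_all = int(sum(m.sum() for m in all_mask.values()))
    den_coding = int(sum(m.sum() for m in coding_mask.values()))
    from .model import NONSYN_CLASSES  # classification list, not an algorithm

    truth_rows = []
    for i, plan in enumerate(plans):
        sample = plan.sample_id
        n_consensus = 0
        num_all = 0
        num_coding = 0
        if plan.has_dna:
            split_keys: Dict[tuple, str] = {}
            for key, entry in truth_support.get(sample, {}).items():
                retained = len(entry["callers"]) >= 2 or entry["hotspot"]
                if not retained or entry["germline_leak"]:
                    continue
                n_consensus += 1
                chrom, pos, ref, alt = key
                for off in range(len(ref)):  # MNV split, per-base tally
                    split_keys.setdefault((chrom, pos + off, ref[off], alt[off]),
                                          entry["vclass"])
            for (chrom, pos, ref, alt), vclass in split_keys.items():
                if all_mask[chrom][pos - 1]:
                    num_all += 1
                if vclass in NONSYN_CLASSES and coding_mask[chrom][pos - 1]:
                    num_coding += 1
        truth_rows.append({
            "tumor_event_id": plan.event_id,
            "sample_id": sample,
            "expected_subtype": "" if plan.expected_subtype is None
            else plan.expected_subtype,
            "methyl_gated": plan.methyl_gated,
            "expected_consensus_n": n_consensus,
            "expected_tmb_all": num_all / (den_all / 1e6) if plan.has_dna else "",
            "expected_tmb_coding": num_coding / (den_coding / 1e6)
            if plan.has_dna else "",
        })
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return GeneratedCohort(directory=outdir, plans=plans, truth=truth)
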