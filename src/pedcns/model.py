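"""Domain types shared by every pipeline stage.

Coordinate conventions: :class:`VariantRecord` keeps MAF-native 1-based
inclusive coordinates; all interval types (:mod:`pedcns.intervals`,
:class:`CnvSegment`) are 0-based half-open. Conversion happens only in the
readers/writers (:mod:`pedcns.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, List, Optional, Sequence, Tuple

import yaml

from .intervals import GenomicInterval

SNV_CALLERS = ("strelka2", "mutect2", "lancet", "vardict")
CNV_CALLERS = ("controlfreec", "cnvkit", "gatk", "mantasv")
FUSION_CALLERS = ("arriba", "starfusion", "dgd_panel")

CNV_STATUSES = ("deep deletion", "loss", "neutral", "gain", "amplification")

#: MAF Variant_Classification values counted as nonsynonymous (high/moderate
#: consequence) in the coding TMB numerator.
NONSYN_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Nonsense_Mutation",
        "In_Frame_Del",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

#: Classifications treated as loss-of-function by the subtyping rules.
LOF_CLASSES = frozenset(
    {
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

MNP_TYPES = frozenset({"DNP", "TNP", "ONP"})


def normalize_chrom(chrom: str) -> str:
    """Canonical 'chr'-prefixed chromosome name."""
    chrom = str(chrom).strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    if not chrom.startswith("chr"):
        chrom = "chr" + chrom
    return chrom


@dataclass(frozen=True)
class VariantRecord:
    """One somatic small-variant call in MAF coordinates (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    variant_class: str = ""
    variant_type: str = "SNP"
    gene: str = ""
    protein_change: str = ""
    callers: FrozenSet[str] = frozenset()
    t_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    n_depth: Optional[int] = None
    gnomad_af: Optional[float] = None
    hotspot: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for variant at {self.chrom}:{self.start}")
        if (
            self.alt_depth is not None
            and self.t_depth is not None
            and self.alt_depth > self.t_depth
        ):
            raise ValueError("alt_depth exceeds t_depth")
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError(f"gnomad_af outside [0,1]: {self.gnomad_af}")

    @property
    def key(self) -> Tuple[str, str, int, int, str, str]:
        """Identity used for cross-caller matching."""
        return (self.sample_id, self.chrom, self.start, self.end, self.ref, self.alt)

    def with_callers(self, callers: FrozenSet[str]) -> "VariantRecord":
        return replace(self, callers=callers)


@dataclass(frozen=True)
class ConsensusVariant:
    """A variant retained in the multi-caller consensus."""

    record: VariantRecord
    consensus_reason: str  # "multi_caller" | "hotspot_rescue"
    mnp_members: Tuple[Tuple[str, str, int, int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.consensus_reason == "multi_caller":
            if len(self.record.callers) < 2:
                raise ValueError("multi_caller consensus requires >= 2 callers")
        elif self.consensus_reason == "hotspot_rescue":
            if not self.record.hotspot:
                raise ValueError("hotspot_rescue requires hotspot flag")
        else:
            raise ValueError(f"unknown consensus_reason: {self.consensus_reason}")

    @property
    def key(self):
        return self.record.key


@dataclass(frozen=True)
class CnvSegment:
    """One copy-number segment from a single caller."""

    sample_id: str
    interval: GenomicInterval
    caller: str
    copy_number: Optional[int] = None
    status: str = "neutral"

    def __post_init__(self) -> None:
        if self.status not in CNV_STATUSES:
            raise ValueError(f"unknown CNV status: {self.status!r}")
        if self.copy_number is not None and self.copy_number < 0:
            raise ValueError("negative copy number")

    @property
    def direction(self) -> Optional[str]:
        """'gain', 'loss', or None for neutral segments."""
        if self.status in ("gain", "amplification"):
            return "gain"
        if self.status in ("loss", "deep deletion"):
            return "loss"
        return None


def status_from_copy_number(cn: int, ploidy: int = 2) -> str:
    """Direction status from an integer copy number.

    cn=0 -> deep deletion; cn<ploidy -> loss; cn=ploidy -> neutral;
    ploidy<cn<ploidy+3 -> gain; cn>=ploidy+3 -> amplification. The mapping
    is a documented stand-in kept in one place so it can be reconfigured.
    """
    if cn < 0:
        raise ValueError("negative copy number")
    if cn == 0:
        return "deep deletion"
    if cn < ploidy:
        return "loss"
    if cn == ploidy:
        return "neutral"
    if cn < ploidy + 3:
        return "gain"
    return "amplification"


@dataclass(frozen=True)
class FusionCall:
    """One gene-fusion call (5' and 3' partner, caller provenance)."""

    sample_id: str
    gene5: str
    gene3: str
    caller: str
    cancer_group: str = ""
    annotations: FrozenSet[str] = frozenset()

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def name(self) -> str:
        return f"{self.gene5}::{self.gene3}"


@dataclass(frozen=True)
class MethylPrediction:
    """DNA-methylation classifier output for one specimen."""

    sample_id: str
    classifier: str  # "dkfz_v12" | "nih_v2"
    subclass: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score outside [0,1]: {self.score}")


@dataclass(frozen=True)
class SpecimenRecord:
    """One biospecimen row of the histologies/clinical table."""

    sample_id: str
    participant_id: str
    tumor_event_id: str = ""
    experimental_strategy: str = ""
    tumor_descriptor: str = ""
    pathology_diagnosis: str = ""
    pathology_free_text_diagnosis: str = ""
    age_at_diagnosis_years: Optional[float] = None
    germline_flags: FrozenSet[str] = frozenset()
    anatomical_site: str = ""
    cancer_group: str = ""

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        if self.age_at_diagnosis_years is not None and self.age_at_diagnosis_years < 0:
            raise ValueError("negative age at diagnosis")


@dataclass(frozen=True)
class Thresholds:
    """Every literal cutoff used across the pipeline, in one place.

    Units: depths in reads, lengths/gaps in bp, fractions in [0,1],
    expression cutoffs in TPM or z-score units, ages in years.
    """

    normal_depth_max: int = 7
    gnomad_af_min: float = 0.001
    tumor_only_min_t_depth: int = 4
    min_callers: int = 2
    recip_overlap: float = 0.50
    containment: float = 0.90
    max_cnv_per_file: int = 2500
    merge_gap: int = 10_000
    min_cnv_len: int = 3000
    blacklist_overlap: float = 0.50
    methyl_confidence: float = 0.80
    mycn_tpm_cutoff: float = 140.83
    tp53_score_cutoff: float = 0.5
    zscore_high: float = 2.0
    zscore_low: float = -2.0
    mb_age_alpha: float = 2.0
    mb_age_beta_gamma: float = 5.0
    mb_age_delta: float = 10.0
    ploidy: int = 2
    fusion_recurrence_min: int = 3
    arm_event_min_fraction: float = 0.5
    hotspot_column: str = "HotSpotAllele"

    def __post_init__(self) -> None:
        for name in (
            "gnomad_af_min",
            "recip_overlap",
            "containment",
            "blacklist_overlap",
            "methyl_confidence",
            "tp53_score_cutoff",
            "arm_event_min_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {value}")
        for name in (
            "normal_depth_max",
            "tumor_only_min_t_depth",
            "min_callers",
            "max_cnv_per_file",
            "merge_gap",
            "min_cnv_len",
            "ploidy",
            "fusion_recurrence_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__},
                fh,
                sort_keys=True,
            )


@dataclass(frozen=True)
class Tp53Status:
    """Per tumor event TP53 classification with its evidence trace."""

    sample_id: str
    status: str  # "activated" | "lost" | "other"
    evidence_trace: Tuple[str, ...] = ()


@dataclass
class SubtypeResult:
    """Per tumor event molecular subtype plus the rules that fired."""

    tumor_event_id: str
    molecular_subtype: Optional[str]
    fired_rules: List[str] = field(default_factory=list)
    confidence_notes: str = ""
    review_flag: bool = False
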