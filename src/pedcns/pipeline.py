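"""End-to-end pipeline over a directory of standard input tables.

Stage order: SNV consensus -> TMB; CNV consensus -> gene status -> arm
events; fusion prioritization; expression flags; TP53 status; subtype
assignment. Missing evidence channels degrade gracefully: predicates on
absent channels evaluate False and a warning is logged. A run manifest
(input checksums, config hash, per-stage row counts) is written alongside
the outputs; reruns on identical inputs produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Set

import pandas as pd

from . import io as pio
from .consensus_cnv import (
    assign_gene_status,
    gene_status_to_frame,
    regions_to_frame,
    resolve_duplicate_status,
    run_cnv_consensus,
)
from .consensus_snv import run_consensus
from .expression import cohort_zscore, collapse_to_symbol
from .fusion import annotate_oncogenic, fusions_to_frame, retain_fusions
from .intervals import IntervalSet
from .model import NONSYN_CLASSES, Thresholds
from .subtypes import (
    DEFAULT_RULES,
    EvidenceBundle,
    call_arm_events,
    read_arm_table,
    results_to_frame,
    run_subtyping,
)
from .tmb import compute_tmb, split_mnv, tmb_to_frame
from .tp53 import SomaticTp53Variant, Tp53Evidence, classify_tp53, tp53_to_frame

logger = logging.getLogger(__name__)

SNV_FILES = {c: f"{c}.maf.tsv" for c in ("strelka2", "mutect2", "lancet", "vardict")}
SEG_FILES = {c: f"{c}.seg.tsv" for c in ("controlfreec", "cnvkit", "gatk", "mantasv")}
GENE_LIST_FILES = {
    "kinase": "kinase.txt",
    "oncogene": "oncogene.txt",
    "tumor_suppressor": "tsg.txt",
    "transcription_factor": "tf.txt",
    "cosmic_census": "cosmic.txt",
    "tcga_observed": "tcga.txt",
}


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(
    input_dir,
    out_dir,
    thresholds: Thresholds = Thresholds(),
    rules: Dict = DEFAULT_RULES,
) -> Dict:
    """Run every stage on ``input_dir``; returns the manifest dict."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"stages": {}, "inputs": {}}
    for path in sorted(input_dir.iterdir()):
        if path.is_file():
            manifest["inputs"][path.name] = _sha256(path)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(
            {k: getattr(thresholds, k) for k in thresholds.__dataclass_fields__},
            sort_keys=True,
        ).encode()
    ).hexdigest()

    # ---- stage: consensus SNV -------------------------------------------
    per_caller = {}
    for caller, name in SNV_FILES.items():
        path = input_dir / name
        if path.exists():
            per_caller[caller] = pio.read_maf(
                path, caller=caller, hotspot_column=thresholds.hotspot_column
            )
    consensus = run_consensus(per_caller, thresholds) if per_caller else []
    pio.write_consensus_maf(consensus, out_dir / "consensus_snv.maf.tsv")
    manifest["stages"]["consensus_snv"] = {
        "in": sum(len(v) for v in per_caller.values()),
        "out": len(consensus),
    }
    variants_by_sample: Dict[str, list] = {}
    for cv in consensus:
        variants_by_sample.setdefault(cv.record.sample_id, []).append(cv)

    # ---- stage: consensus CNV / gene status / arm events ----------------
    segs = {}
    for caller, name in SEG_FILES.items():
        path = input_dir / name
        if path.exists():
            segs[caller] = pio.read_seg(path, caller=caller, ploidy=thresholds.ploidy)
    blacklist = None
    if (input_dir / "blacklist.bed").exists():
        blacklist = pio.read_bed(input_dir / "blacklist.bed")
    gatk_available = bool(segs.get("gatk"))
    regions = run_cnv_consensus(
        {c: v for c, v in segs.items() if c != "mantasv"},
        blacklist=blacklist,
        gatk_available=gatk_available,
        manta_segments=segs.get("mantasv", ()),
        thresholds=thresholds,
    ) if segs else []
    regions_to_frame(regions).to_csv(
        out_dir / "consensus_cnv.tsv", sep="\t", index=False
    )
    manifest["stages"]["consensus_cnv"] = {
        "in": sum(len(v) for v in segs.values()),
        "out": len(regions),
    }

    dna_samples: Set[str] = set(variants_by_sample)
    for seg_list in segs.values():
        dna_samples.update(s.sample_id for s in seg_list)

    gene_status_by_sample: Dict[str, Dict[str, str]] = {}
    if (input_dir / "genes.bed").exists():
        gene_model = pio.read_gene_bed(input_dir / "genes.bed")
        gene_calls = resolve_duplicate_status(
            assign_gene_status(regions, gene_model, samples=sorted(dna_samples))
        )
        gene_status_to_frame(gene_calls).to_csv(
            out_dir / "gene_status.tsv", sep="\t", index=False
        )
        for call in gene_calls:
            gene_status_by_sample.setdefault(call.sample_id, {})[call.gene] = call.status
        manifest["stages"]["gene_status"] = {"out": len(gene_calls)}
    else:
        logger.warning("no gene model supplied; gene-status stage skipped")

    arm_events_by_sample: Dict[str, set] = {}
    if (input_dir / "arms.tsv").exists():
        arms = read_arm_table(input_dir / "arms.tsv")
        arm_events_by_sample = call_arm_events(regions, arms, thresholds)
        pd.DataFrame(
            [
                {"sample_id": s, "arm": arm, "direction": d}
                for s in sorted(arm_events_by_sample)
                for arm, d in sorted(arm_events_by_sample[s])
            ],
            columns=["sample_id", "arm", "direction"],
        ).to_csv(out_dir / "arm_events.tsv", sep="\t", index=False)

    # ---- stage: TMB ------------------------------------------------------
    surveyed = [
        pio.read_bed(input_dir / f"surveyed_{c}.bed")
        for c in ("strelka2", "mutect2", "vardict")
        if (input_dir / f"surveyed_{c}.bed").exists()
    ]
    if surveyed and (input_dir / "cds.bed").exists() and consensus:
        all_region = surveyed[0]
        for other in surveyed[1:]:
            all_region = all_region.intersect(other)
        coding_region = all_region.intersect(pio.read_bed(input_dir / "cds.bed"))
        split = split_mnv([cv.record for cv in consensus])
        tmb_results = compute_tmb(split, "WGS", all_region, coding_region)
        tmb_to_frame(tmb_results).to_csv(out_dir / "tmb.tsv", sep="\t", index=False)
        manifest["stages"]["tmb"] = {"out": len(tmb_results)}

    # ---- stage: fusion prioritization -----------------------------------
    fusions_by_sample: Dict[str, list] = {}
    if (input_dir / "fusions.tsv").exists():
        fusions = pio.read_fusions(input_dir / "fusions.tsv")
        gene_lists = {}
        for flag, name in GENE_LIST_FILES.items():
            path = input_dir / name
            if path.exists():
                gene_lists[flag] = {
                    line.strip() for line in open(path) if line.strip()
                }
        if gene_lists:
            fusions = annotate_oncogenic(fusions, gene_lists)
        prioritized = retain_fusions(fusions, thresholds)
        fusions_to_frame(prioritized).to_csv(
            out_dir / "fusions_prioritized.tsv", sep="\t", index=False
        )
        for pf in prioritized:
            fusions_by_sample.setdefault(pf.call.sample_id, []).append(pf)
        manifest["stages"]["fusions"] = {"in": len(fusions), "out": len(prioritized)}

    # ---- stage: expression flags ----------------------------------------
    expr_over: Dict[str, set] = {}
    expr_under: Dict[str, set] = {}
    mycn_tpm: Dict[str, float] = {}
    if (input_dir / "expression.tsv").exists():
        matrix = collapse_to_symbol(pio.read_expression(input_dir / "expression.tsv"))
        zscores = cohort_zscore(matrix)
        over = zscores.ge(thresholds.zscore_high)
        under = zscores.lt(thresholds.zscore_low)
        for sample in matrix.columns:
            expr_over[sample] = set(zscores.index[over[sample]])
            expr_under[sample] = set(zscores.index[under[sample]])
        if "MYCN" in matrix.index:
            mycn_tpm = matrix.loc["MYCN"].to_dict()
        manifest["stages"]["expression"] = {"genes": int(matrix.shape[0])}

    # ---- stage: TP53 -----------------------------------------------------
    methyl_by_sample: Dict[str, list] = {}
    if (input_dir / "methyl.tsv").exists():
        for pred in pio.read_methyl(input_dir / "methyl.tsv"):
            methyl_by_sample.setdefault(pred.sample_id, []).append(pred)

    sv_tp53: Set[str] = set()
    if (input_dir / "sv.tsv").exists():
        sv_df = pd.read_csv(input_dir / "sv.tsv", sep="\t", dtype=str)
        sv_tp53 = set(sv_df.loc[sv_df["gene"] == "TP53", "sample_id"])
    tp53_scores: Dict[str, float] = {}
    if (input_dir / "tp53_scores.tsv").exists():
        score_df = pd.read_csv(input_dir / "tp53_scores.tsv", sep="\t")
        tp53_scores = dict(zip(score_df["sample_id"], score_df["score"]))

    specimens = pio.read_histologies(input_dir / "histologies.tsv")
    extra = pd.read_csv(
        input_dir / "histologies.tsv", sep="\t", dtype=str, keep_default_na=False
    ).set_index("sample_id")

    tp53_by_sample = {}
    for spec in specimens:
        somatic = tuple(
            SomaticTp53Variant(cv.record.protein_change, cv.record.hotspot)
            for cv in variants_by_sample.get(spec.sample_id, [])
            if cv.record.gene == "TP53"
            and (cv.record.variant_class in NONSYN_CLASSES or cv.record.hotspot)
        )
        evidence = Tp53Evidence(
            sample_id=spec.sample_id,
            somatic_variants=somatic,
            cnv_loss=gene_status_by_sample.get(spec.sample_id, {}).get("TP53")
            in ("loss", "deep deletion"),
            sv=spec.sample_id in sv_tp53,
            germline_lfs_variant=bool(
                {"TP53_LFS", "TP53"} & spec.germline_flags
            ),
            classifier_score=tp53_scores.get(spec.sample_id),
        )
        tp53_by_sample[spec.sample_id] = classify_tp53(evidence, thresholds)
    tp53_to_frame([tp53_by_sample[s.sample_id] for s in specimens]).to_csv(
        out_dir / "tp53_status.tsv", sep="\t", index=False
    )

    # ---- stage: subtyping ------------------------------------------------
    bundles: List[EvidenceBundle] = []
    for spec in specimens:
        s = spec.sample_id
        bundles.append(
            EvidenceBundle(
                specimen=spec,
                variants=variants_by_sample.get(s, []),
                gene_status=gene_status_by_sample.get(s, {}),
                arm_events=arm_events_by_sample.get(s, set()),
                fusions=fusions_by_sample.get(s, []),
                expr_over=expr_over.get(s, set()),
                expr_under=expr_under.get(s, set()),
                mycn_tpm=mycn_tpm.get(s),
                methyl=methyl_by_sample.get(s, []),
                tp53=tp53_by_sample.get(s),
                rna_mb_label=extra.loc[s].get("rna_mb_label", "") if s in extra.index else "",
                prior_subtype=extra.loc[s].get("prior_subtype", "") if s in extra.index else "",
                thresholds=thresholds,
            )
        )
    results = run_subtyping(bundles, rules)
    results_to_frame(results).to_csv(out_dir / "subtypes.tsv", sep="\t", index=False)
    manifest["stages"]["subtype"] = {"out": len(results)}

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
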