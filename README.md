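# pedcns

Consensus somatic calling, tumor mutational burden, and rule-based
WHO 2021 molecular subtyping for pediatric CNS (and neuroblastoma) tumor
cohorts.

Large pediatric cancer atlases harmonize somatic calls from several
independent callers, integrate them with fusion, expression, and DNA
methylation evidence, and assign research-grade molecular subtypes per
tumor event. `pedcns` implements that downstream computation as a tested,
reusable Python library with a thin CLI, operating entirely on standard
tabular formats (MAF, SEG-like TSV, BED, TSV matrices). A synthetic
cohort generator with injected, labeled lesions makes every stage
verifiable without any data download.

## What it computes

**SNV consensus.** Per-caller MAFs (Strelka2, Mutect2, Lancet, VarDict)
are merged on the key *(sample, chrom, start, end, ref, alt)*. A call is
retained iff it is reported by ≥ 2 callers or carries a `HotSpotAllele`
flag. Strelka2 reports multi-nucleotide substitutions as runs of adjacent
SNPs; any MNP from another caller whose every base is matched by
consecutive Strelka2 SNPs is reconstructed into a single Strelka2 MNP
before merging. Likely germline leakage is then removed:
a non-hotspot variant is dropped iff *n_depth ≤ 7* and *gnomAD AF > 0.001*.
Tumor-only calls are pre-filtered with *alt_depth = 0 ∨ t_depth < 4*.

**CNV consensus and focal status.** Per sample and direction, two
callers' segments reach consensus by reciprocal overlap ≥ 50% (the
intersection is emitted) or >90% containment of the smaller segment.
Noisy (sample, caller) files with > 2,500 segments are dropped; consensus
regions within 10 kb merge; regions < 3 kb or ≥ 50% inside an
IgH/telomere/centromere/segmental-duplication blacklist are removed.
Gene-level status calls are resolved to one per (sample, gene) by
(1) non-neutral over neutral, (2) dominant gene overlap,
(3) amplification/deep deletion over gain/loss.

**TMB.** After splitting MNVs into per-base SNVs and de-duplicating,

    TMB_all    = #mutations in surveyed region / (surveyed bp / 10^6)
    TMB_coding = #nonsynonymous mutations in (surveyed ∩ CDS) / (bp / 10^6)

where the WGS surveyed region is the intersection of the callers'
effectively surveyed BEDs.

**Fusion prioritization, TP53 status, subtyping.** Fusions are kept when
called by both RNA callers, recurrent or specific to a cancer group, or
putative-oncogenic (a partner on a kinase / oncogene / tumor suppressor /
transcription factor / COSMIC / TCGA list). TP53 status is *activated*
for p.R273C/p.R248W, else *lost* for a hotspot mutation, two distinct
alterations, a single somatic or germline-LFS variant, or germline LFS
plus an inactivation-classifier score > 0.5. A per-histology ordered rule
engine (HGG/IHG, ATRT, NBL, CRANIO, EPN, LGG, MB with SHH α/β/γ/δ, PB,
ETMR) integrates mutations, focal and arm-level copy number, fusions,
expression z-scores (over: z ≥ 2; under: z < −2), raw MYCN TPM
(cutoff 140.83), and DKFZ methylation classes gated at score ≥ 0.8.

## Worked example

```bash
pedcns make-fixtures --out demo/inputs --seed 42
pedcns run-pipeline --input-dir demo/inputs --out-dir demo/results
```

prints

```
wrote fixture cohort (91 events) to demo/inputs
pipeline complete: 7 stages
```

and `demo/results/subtypes.tsv` starts

```
tumor_event_id    molecular_subtype         fired_rules                   review_flag
hgg_dmg_mutation  DMG, H3 K28               hgg_dmg_k28_mutation          False
hgg_dmg_methyl    DMG, H3 K28               hgg_dmg_methylation           False
hgg_oligo_idh     Oligo, IDH-mutant         hgg_oligo_idh_methylation     False
```

Each row is one tumor event; `fired_rules` is the audit trail of the
first matching rule. `demo/results/tmb.tsv` holds per-sample burdens,
e.g. sample BS_0001 with 7 consensus mutations over a 69.79 Mb surveyed
toy-genome denominator gives `tmb_all_per_mb = 0.1003...`. The generated
`truth.tsv` in the input directory records, for every event, the injected
lesion's expected subtype and brute-force consensus/TMB tallies, so the
outputs can be checked line by line.

## Layout

- `pedcns.intervals`, `pedcns.model`, `pedcns.io` — interval algebra,
  domain types, thresholds, and format readers/writers
- `pedcns.consensus_snv`, `pedcns.consensus_cnv`, `pedcns.tmb`,
  `pedcns.fusion`, `pedcns.tp53`, `pedcns.expression`,
  `pedcns.independent` — the analysis stages
- `pedcns.subtypes` — evidence bundles, arm events, and the per-histology
  rule sets (label strings and gene lists live in
  `pedcns.subtypes.ruleconfig`, overridable via YAML)
- `pedcns.fixtures` — the synthetic cohort generator
- `pedcns.pipeline`, `pedcns.cli` — end-to-end orchestration and the
  `pedcns` command

See `docs/methods.md` for the full description of the procedures, their
parameters, and known limitations.
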