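# Methods

This note documents the procedures implemented in `pedcns`, the
parameters that matter, the design choices made where the design was
genuinely open, what the synthetic cohorts do and do not emulate, and the
package's known limitations.

## Coordinate and data conventions

Small variants are kept in MAF-native 1-based inclusive coordinates; all
interval arithmetic (surveyed regions, CNV segments, BED inputs) uses
0-based half-open coordinates. Conversion happens exactly once, at the
reader boundary. Chromosome names are normalized to the `chr`-prefixed
form. An `IntervalSet` stores per-chromosome sorted, merged, disjoint
intervals; abutting intervals merge, so `total_bp` is the exact covered
base count. Set intersection is a two-pointer sweep; tests verify both
against per-base bit masks on toy genomes.

## SNV consensus

Variant identity is the tuple *(sample, chrom, start, end, ref, alt)*;
representation normalization (left-alignment) is assumed to have been
done upstream by the annotator. Retention requires support from at least
`min_callers = 2` of {strelka2, mutect2, lancet, vardict}, or a hotspot
flag from any single caller. When callers disagree on depths or
annotations for a shared key, the record is donated by a fixed priority
(strelka2 > mutect2 > lancet > vardict) — the choice is arbitrary but
deterministic.

MNP reconstruction: Strelka2 emits multi-base substitutions as adjacent
SNPs. For every DNP/TNP/ONP reported by another caller, the module looks
for a complete run of Strelka2 SNPs matching each constituent base
(position, ref, alt). A complete match replaces those SNPs with one
Strelka2 MNP identical in span and alleles. When overlapping candidates
compete for the same SNP, the longest candidate wins, ties broken
leftmost — maximal merges best preserve the predicted protein change.
The merged record takes its depths from the leftmost constituent SNP.
Substituted base count is conserved by construction and asserted by a
randomized test.

Germline leakage: a retained non-hotspot variant is removed iff its
matched-normal depth ≤ 7 reads *and* its gnomAD allele frequency
> 0.001. Absent normal depth (tumor-only) or absent frequency never
triggers removal, so the filter is a no-op for tumor-only samples — those
are instead pre-filtered by *alt_depth = 0 ∨ t_depth < 4* (both
boundaries tested exhaustively).

## CNV consensus

Only non-neutral segments participate. Amplification and deep deletion
enter the comparison as gain and loss respectively; the extreme status is
preserved on the output region whenever any supporter carried it. The two
consensus rules per same-sample, same-direction caller pair:

1. reciprocal overlap ≥ `recip_overlap` (0.50) on **both** sides — the
   intersection interval is emitted. The choice of intersection (rather
   than union or one caller's segment) is conservative and caller-order
   independent.
2. otherwise, if the smaller segment is covered > `containment` (0.90) by
   the larger — the smaller segment is emitted. "Fraction of the smaller
   region's length" is an interpretation; it is the only reading under
   which rule 2 extends rule 1.

De-noising drops any (sample, caller) file with more than
`max_cnv_per_file = 2500` non-neutral segments (boundary: 2,500 kept,
2,501 dropped); neutral segments are not counted. When no GATK panel of
normals exists, MantaSV-derived segments substitute as the third caller
next to Control-FREEC and CNVkit. Same-direction regions within
`merge_gap = 10,000` bp (inclusive) merge, unioning supporters; the copy
number of a merged or consensus region is donated by caller priority
controlfreec > cnvkit > gatk > mantasv. Finally, regions shorter than
`min_cnv_len = 3000` bp or with ≥ `blacklist_overlap = 0.50` of their
length in the blacklist are removed. Neutral regions of samples included
in the consensus have their copy number reported as NA; WXS CNVkit calls
are appended verbatim and flagged non-consensus.

The copy-number → status map used when a SEG file lacks a status column
(0 → deep deletion, < ploidy → loss, = ploidy → neutral, < ploidy+3 →
gain, ≥ ploidy+3 → amplification, default ploidy 2, sex chromosomes
treated identically unless a per-sample ploidy is configured) is a
stand-in kept in one configurable place: upstream callers do not document
a canonical map.

## Gene-level focal status

Every (gene, overlapping consensus region) pair yields a candidate call
annotated with the overlap in bp; genes overlapped by no region are
neutral (the consensus file omits neutral regions, so absence is absence
of evidence). Duplicates resolve by, in order: non-neutral over neutral;
largest gene overlap; amplification over gain and deep deletion over
loss; then a deterministic (status rank, segment start) tie-break that
closes the residue the first three rules leave. Resolution is therefore
total by construction, and asserted on randomized inputs.

## Tumor mutational burden

MNVs are split into per-base SNVs inheriting sample and classification,
then de-duplicated per sample. The all-mutation numerator counts every
consensus mutation whose position lies in the surveyed denominator
region; the coding numerator additionally requires a nonsynonymous
classification (Missense, Frame_Shift_Del/Ins, In_Frame_Del/Ins,
Splice_Site, Nonsense, Nonstop, Translation_Start_Site) and position
inside the surveyed ∩ CDS region. Denominators are `IntervalSet.total_bp`
of those regions; for WGS all surveyed BEDs given are intersected.
Mutations-per-bp ratios are reported per megabase (×10⁶), the field
standard; raw numerators and denominators are emitted alongside so the
unscaled ratio is recoverable. An alternate nonsynonymous classification
set (the TMB-harmonization flavor) ships as an editable constant behind
the `nonsyn_filter` parameter; its default membership is configuration,
not a claim about any external project's exact list.

## Fusion prioritization

Input calls are assumed already artifact-filtered upstream. A fusion is
putative-oncogenic iff either partner appears on any configured gene list
(kinase, oncogene, tumor suppressor, curated transcription factor, COSMIC
census, TCGA-observed). Retention: called by both RNA callers in the same
sample; or the gene pair seen in ≥ `fusion_recurrence_min = 3` samples of
one cancer group (the threshold is a documented stand-in — no canonical
value exists); or the pair restricted to exactly one cancer group
cohort-wide; or putative-oncogenic. Clinical panel (DGD) calls bypass
filtering. Output is sorted and independent of input row order.

## TP53 status

*Activated* iff any somatic variant is p.R273C or p.R248W. Otherwise
*lost* iff any of: (i) a hotspot TP53 mutation; (ii) ≥ 2 distinct TP53
alterations counting each somatic variant, focal loss, and SV once;
(iii) any single somatic TP53 variant or a pathogenic germline LFS
variant; (iv) germline LFS variant and inactivation-classifier score
> 0.5. Activated takes precedence: the gain-of-function residues are
themselves hotspots and would otherwise satisfy (i). Condition (iii) is
deliberately permissive (any nonsynonymous somatic variant suffices,
without a pathogenicity filter) — the somatic variants passed in are
pre-filtered to nonsynonymous classes or hotspot flags. Hotspot and
domain catalogs are inputs, not embedded. The classifier itself (an
RNA-based inactivation signature) is consumed as a score column.

## Expression support

Duplicate gene symbols collapse to the row with maximal mean across
samples after discarding all-zero rows; ties break on lexicographic
Ensembl id. Collapse is idempotent. Z-scores are computed on
log2(x+1)-transformed values per gene within a cohort group using the
population (n) standard deviation; constant and single-sample cohorts get
z = 0. The cohort grouping defaults to one group and is intended to be
(cancer group × RNA library type) when metadata is supplied, mirroring
the batch-avoidance principle used for expression scoring. Over-expression
is z ≥ 2 (inclusive); under-expression is z < −2 (strict) — the criteria
quote the boundaries with exactly that asymmetry. The NBL MYCN decision
uses raw collapsed TPM against 140.83, not a z-score. Marker genes cited
without a numeric criterion (TKTL1, EZHIP, GPBP1, IFT46, LIN28A) use the
z ≥ 2 flag as a documented stand-in.

## Subtyping engine

Evidence per tumor event is assembled into a bundle (clinical record,
consensus variants with protein changes, gene-level CN status, arm
events, prioritized fusions, expression flags and raw MYCN TPM,
methylation predictions, TP53 status, optional external MB RNA label and
prior subtype). Every channel is optional; predicates on absent channels
evaluate False, so mixed-platform cohorts degrade gracefully rather than
erroring.

Arm events: an arm is gained (lost) when merged same-direction consensus
regions cover ≥ `arm_event_min_fraction = 0.5` of the arm, using a
supplied arm coordinate table. Merging before measuring prevents double
counting of overlapping regions.

Within each histology the published criteria order is the rule priority;
the first match wins. Methylation rules require a classifier score
≥ `methyl_confidence = 0.80` (inclusive); the IHG gate is the classifier
label itself without a score gate, as its definition does not state one.
Fall-throughs end in ", To be classified"; SHH medulloblastomas with no
subgroup evidence keep the unrefined "MB, SHH". For HGG, TP53 status
(lost/activated) is appended to the label as a ", TP53 …" suffix — the
exact string form is a project convention, configurable.

MB SHH subgroups α/β/γ/δ: a high-confidence MB_SHH_1/2/3/4 methylation
class decides directly (β/γ/α/δ respectively); otherwise age-gated
molecular criteria apply (α: age ≥ 2 y; β, γ: age < 5 y; δ: age ≥ 10 y).
The criteria are not mutually exclusive (a 2p gain at age 3 matches both
β and γ). Precedence is by specificity, operationalized as the number of
alternative criteria bullets defining the subgroup (γ: 1 < β, δ: 3 < α:
4) — fewer alternatives is the more specific claim — with residual ties
broken α > β > γ > δ. This reproduces γ for the 2p-gain case while
leaving single-subgroup lesions unaffected. "Loss of function" means
Variant_Classification ∈ {Nonsense, Frame_Shift_Del/Ins, Splice_Site,
Nonstop, Translation_Start_Site}; hotspot TERT/U1 evidence is read from
the hotspot flag plus a configured gene list. "Chromosome 19
amplification" for ETMR is operationalized as an arm-level gain on 19p or
19q. Spinal/posterior-fossa location is read from a metadata column,
with the methylation class as the alternative route where a rule lists
one. When methylation and RNA MB labels disagree, methylation wins and
the event is flagged for review, as is an NBL free-text/genetics
conflict; the package never auto-overrides pathology.

Label strings, methylation-class maps, marker-gene lists and the
histology dispatch keywords are data (`pedcns.subtypes.ruleconfig`),
overridable from YAML without code changes; the boolean structure of the
rules is code. Punctuation and casing of released label strings vary
between data releases; the defaults use the forms quoted in the criteria.

## Independent-specimen selection

One biospecimen per participant, after an experimental-strategy filter,
preferring tumor descriptors in the order Initial CNS Tumor / Primary
Tumor > Progressive > Recurrence > others, ties broken by lexicographic
sample id. The preference order is configurable per analysis; the default
is a documented convention.

## Synthetic cohorts

The generator emulates every input format on a toy genome of seven 10-Mb
chromosomes (p arm 0–4.5 Mb, q arm 5–10 Mb). Marker genes occupy the
distal q arms so that arm-event segments (covering the proximal 60% of an
arm) never intersect them — lesions compose without cross-talk. The
rule-covering cohort holds 91 tumor events, at least one per rule per
histology, each with exactly one defining lesion; per-caller MAFs add
shared passengers (3 callers), private passengers (1 caller, expected to
drop), germline-leakage variants (shallow normal + gnomAD 0.01, expected
to drop), and one constructed Strelka2-SNP-pair / Mutect2-DNP case.
Expression lesions are encoded as a 100-fold outlier over a flat TPM
baseline, which yields |z| ≫ 2 in the ~80-sample RNA cohort.

Truth values are computed by naive brute force inside the generator —
support-set tallies for the consensus, per-bp numpy masks for region
sizes and TMB, the planned label for subtypes — never by the library
under test. What the fixtures do **not** emulate: realistic mutation
rates or signatures, subclonal copy-number, overlapping multi-lesion
events, caller-specific error profiles, batch effects across RNA library
types, or genome-scale data volumes. Passing tests therefore demonstrate
the correctness of the documented logic, not calibration on real tumors.

Problem sizes used by the test suite and acceptance script — 4 × ~1,000
random variants for the SNV oracle, 3 × 200 segments × 20 samples for the
CNV oracle, 1,000 random MNP cases, a 144-row TP53 truth table, the
91-event cohort end-to-end twice — were chosen so every oracle comparison
is exact and exhaustive at desk scale.

## Numerical choices and degenerate inputs

Exact integer bp arithmetic everywhere in interval code; TMB ratios are
the only floating-point quantities and are reported alongside their
integer numerators/denominators. Boundary semantics follow the quoted
criteria: ≥ 2 callers; normal depth ≤ 7; AF > 0.001 strict; reciprocal
overlap ≥ 0.5; containment > 0.9 strict; merge gap ≤ 10,000; length
< 3,000 removed; blacklist fraction ≥ 0.5 removed; methylation score
≥ 0.8; MYCN TPM ≥ 140.83; classifier score > 0.5 strict; z ≥ 2 / z < −2.
Zero denominators raise; empty inputs yield empty outputs; unknown
chromosomes in arm calling are ignored with a warning; files with fewer
than two CNV callers produce an empty consensus with a warning.

## Known limitations

- The engine assigns one bundle per tumor event; multi-biospecimen events
  must be pre-aggregated onto one identifier by the caller.
- Condition-specific catalogs (hotspots, functional domains, gene lists,
  the U1 position list) are inputs; the package ships no curated copies.
- The cn → status map, the fusion recurrence threshold, the expression
  stand-in thresholds, and the exact label strings are conventions
  exposed in configuration rather than facts fixed by the method.
- WXS TMB is supported by the same code path (capture BED as surveyed
  region) but the shipped fixtures exercise WGS only.
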