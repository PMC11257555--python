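"""CNV consensus: de-noise, pairwise/containment rules, merging, filtering,
gene-level focal status resolution; O(n^2) brute-force oracle."""

import pytest

from pedcns.consensus_cnv import (
    ConsensusCnvRegion,
    GeneStatusCall,
    assign_gene_status,
    blacklist_and_size_filter,
    consensus_with_fallback,
    denoise_caller_files,
    merge_adjacent,
    neutral_to_na,
    pairwise_consensus,
    resolve_duplicate_status,
)
from pedcns.fixtures import random_cnv_cohort
from pedcns.intervals import GenomicInterval, IntervalSet
from pedcns.model import CnvSegment, Thresholds

THR = Thresholds()


def seg(start, end, status, caller, sample="BS1", chrom="chr1", cn=None):
    return CnvSegment(
        sample_id=sample,
        interval=GenomicInterval(chrom, start, end),
        caller=caller,
        copy_number=cn,
        status=status,
    )


class TestDenoise:
    def make(self, n, caller="cnvkit"):
        return [seg(i * 10_000, i * 10_000 + 5000, "gain", caller) for i in range(n)]

    def test_boundary_2500_kept(self):
        out = denoise_caller_files({"cnvkit": self.make(2500)}, THR)
        assert len(out["cnvkit"]) == 2500

    def test_2501_dropped(self):
        out = denoise_caller_files({"cnvkit": self.make(2501)}, THR)
        assert out["cnvkit"] == []

    def test_empty_group_kept(self):
        assert denoise_caller_files({"cnvkit": []}, THR) == {"cnvkit": []}


class TestPairwiseConsensus:
    def test_reciprocal_boundary_emits_intersection(self):
        per = {
            "controlfreec": [seg(100_000, 200_000, "gain", "controlfreec")],
            "cnvkit": [seg(150_000, 250_000, "gain", "cnvkit")],
        }
        out = pairwise_consensus(per, THR)
        assert len(out) == 1
        region = out[0]
        assert (region.interval.start, region.interval.end) == (150_000, 200_000)
        assert region.supporting_callers == frozenset({"controlfreec", "cnvkit"})

    def test_containment_emits_smaller_segment(self):
        per = {
            "controlfreec": [seg(0, 10_000, "gain", "controlfreec")],
            "cnvkit": [seg(1000, 2000, "gain", "cnvkit")],
        }
        out = pairwise_consensus(per, THR)
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (1000, 2000)

    def test_direction_mismatch_no_consensus(self):
        per = {
            "controlfreec": [seg(0, 10_000, "gain", "controlfreec")],
            "cnvkit": [seg(0, 10_000, "loss", "cnvkit")],
        }
        assert pairwise_consensus(per, THR) == []

    def test_extreme_status_preserved(self):
        per = {
            "controlfreec": [seg(0, 10_000, "amplification", "controlfreec", cn=9)],
            "cnvkit": [seg(0, 10_000, "gain", "cnvkit", cn=3)],
        }
        out = pairwise_consensus(per, THR)
        assert out[0].direction == "gain"
        assert out[0].status == "amplification"
        assert out[0].copy_number == 9  # donor priority: controlfreec first

    def test_oracle_equivalence_random(self):
        from oracles import brute_force_cnv_consensus

        per_caller = random_cnv_cohort(seed=9, n_samples=20, segments_per_caller=200)
        out = pairwise_consensus(per_caller, THR)
        got = {
            (
                r.sample_id,
                (r.interval.chrom, r.interval.start, r.interval.end),
                r.direction,
                r.supporting_callers,
            )
            for r in out
        }
        assert got == brute_force_cnv_consensus(per_caller, THR)


class TestFallback:
    def test_delegates_to_trio(self):
        per = {
            "controlfreec": [seg(0, 10_000, "gain", "controlfreec")],
            "cnvkit": [seg(0, 10_000, "gain", "cnvkit")],
            "gatk": [],
        }
        out = consensus_with_fallback(per, gatk_available=True)
        assert len(out) == 1

    def test_manta_substitution(self):
        per = {"controlfreec": [seg(0, 10_000, "gain", "controlfreec")], "cnvkit": []}
        manta = [seg(0, 10_000, "gain", "mantasv")]
        out = consensus_with_fallback(per, gatk_available=False, manta_segments=manta)
        assert out[0].supporting_callers == frozenset({"controlfreec", "mantasv"})

    def test_single_caller_empty(self):
        per = {"controlfreec": [seg(0, 10_000, "gain", "controlfreec")]}
        assert consensus_with_fallback(per, gatk_available=True) == []


def region(start, end, direction, sample="BS1", chrom="chr1",
           callers=("controlfreec", "cnvkit"), extreme=None):
    return ConsensusCnvRegion(
        sample_id=sample,
        interval=GenomicInterval(chrom, start, end),
        direction=direction,
        supporting_callers=frozenset(callers),
        extreme_status=extreme,
    )


class TestMergeAdjacent:
    def test_gap_boundary_10kb_merges(self):
        out = merge_adjacent([region(0, 5000, "gain"), region(15_000, 20_000, "gain")], THR)
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (0, 20_000)

    def test_gap_10001_not_merged(self):
        out = merge_adjacent([region(0, 5000, "gain"), region(15_001, 20_000, "gain")], THR)
        assert len(out) == 2

    def test_direction_mismatch_never_merges(self):
        out = merge_adjacent([region(0, 5000, "gain"), region(5001, 9000, "loss")], THR)
        assert len(out) == 2

    def test_no_close_same_direction_pairs_after_merge(self):
        regions = [region(i * 7000, i * 7000 + 5000, "gain") for i in range(20)]
        out = merge_adjacent(regions, THR)
        gains = sorted(
            (r for r in out if r.direction == "gain"), key=lambda r: r.interval.start
        )
        for a, b in zip(gains, gains[1:]):
            assert b.interval.start - a.interval.end > THR.merge_gap


class TestBlacklistSizeFilter:
    def test_short_region_removed(self):
        out = blacklist_and_size_filter([region(0, 2999, "gain")], None, THR)
        assert out == []

    def test_blacklist_half_overlap_removed(self):
        bl = IntervalSet([GenomicInterval("chr1", 0, 5000)])
        out = blacklist_and_size_filter([region(0, 10_000, "gain")], bl, THR)
        assert out == []

    def test_both_conditions_fail_at_boundary_kept(self):
        bl = IntervalSet([GenomicInterval("chr1", 0, 1499)])
        out = blacklist_and_size_filter([region(0, 3000, "gain")], bl, THR)
        assert len(out) == 1

    def test_postconditions_hold_exhaustively(self):
        bl = IntervalSet([GenomicInterval("chr1", 0, 100_000)])
        regions = [region(i * 1000, i * 1000 + 500 + i * 700, "gain") for i in range(60)]
        for r in blacklist_and_size_filter(regions, bl, THR):
            assert r.interval.length >= THR.min_cnv_len
            assert bl.overlap_bp(r.interval) / r.interval.length < THR.blacklist_overlap


class TestNeutralAndWxs:
    def test_neutral_to_na(self):
        segs = [
            seg(0, 1000, "neutral", "cnvkit", cn=2),
            seg(0, 1000, "gain", "cnvkit", cn=4),
        ]
        out = neutral_to_na(segs, {"BS1"})
        assert out[0].copy_number is None
        assert out[1].copy_number == 4

    def test_append_wxs_identity_and_schema(self):
        import pandas as pd

        from pedcns.consensus_cnv import append_wxs_calls, regions_to_frame

        consensus = regions_to_frame([region(0, 10_000, "gain")])
        assert append_wxs_calls(consensus, pd.DataFrame()).equals(consensus)
        wxs = pd.DataFrame(
            [{"sample_id": "BS2", "chrom": "chr1", "start": 0, "end": 5000,
              "status": "gain", "direction": "gain", "copy_number": 4,
              "callers": "cnvkit"}] * 2
        )
        combined = append_wxs_calls(consensus, wxs)
        assert len(combined) == len(consensus) + 2
        assert list(combined.columns) == list(consensus.columns)
        assert not combined["in_consensus"].iloc[-1]


GENES = {
    "GENEA": GenomicInterval("chr1", 1000, 2000),
    "GENEB": GenomicInterval("chr1", 5000, 6000),
}


class TestGeneStatus:
    def test_gene_inside_gain(self):
        calls = assign_gene_status([region(0, 3000, "gain")], GENES)
        by_gene = {c.gene: c for c in calls}
        assert by_gene["GENEA"].status == "gain"
        assert by_gene["GENEB"].status == "neutral"

    def test_gene_overlapping_two_regions_yields_two_calls(self):
        calls = assign_gene_status(
            [region(0, 1500, "gain"), region(1500, 3000, "loss")], GENES
        )
        genea = [c for c in calls if c.gene == "GENEA"]
        assert sorted(c.status for c in genea) == ["gain", "loss"]

    def test_resolution_priority_rules(self):
        def call(status, overlap, start=0):
            return GeneStatusCall(
                "BS1", "GENEA", status,
                GenomicInterval("chr1", start, start + 1000), overlap,
            )

        # rule 1: non-neutral beats neutral
        assert resolve_duplicate_status(
            [call("neutral", 1000), call("gain", 10)]
        )[0].status == "gain"
        # rule 2: dominant overlap
        assert resolve_duplicate_status(
            [call("gain", 800), call("loss", 200)]
        )[0].status == "gain"
        # rule 3: amplification over gain at equal overlap
        assert resolve_duplicate_status(
            [call("gain", 500), call("amplification", 500)]
        )[0].status == "amplification"
        assert resolve_duplicate_status(
            [call("loss", 500), call("deep deletion", 500)]
        )[0].status == "deep deletion"

    def test_resolution_rate_is_total(self):
        regions = [
            region(0, 1500, "gain"),
            region(1200, 2500, "loss"),
            region(900, 1800, "gain", extreme="amplification"),
            region(4000, 7000, "loss"),
        ]
        calls = assign_gene_status(regions, GENES)
        resolved = resolve_duplicate_status(calls)
        pairs = [(c.sample_id, c.gene) for c in resolved]
        assert len(pairs) == len(set(pairs)) == 2
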