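"""SNV consensus: MNP reconstruction, retention rules, depth/germline filters."""

import numpy as np
import pytest

from pedcns.consensus_snv import (
    call_consensus,
    filter_germline_leakage,
    filter_tumor_only,
    reconstruct_mnp,
    run_consensus,
)
from pedcns.fixtures import random_snv_cohort
from pedcns.model import ConsensusVariant, Thresholds, VariantRecord

THR = Thresholds()


def snp(pos, ref, alt, sample="BS1", chrom="chr1", caller="strelka2", **kw):
    return VariantRecord(
        sample_id=sample, chrom=chrom, start=pos, end=pos, ref=ref, alt=alt,
        variant_type="SNP", variant_class="Missense_Mutation",
        callers=frozenset({caller}), t_depth=kw.pop("t_depth", 100),
        alt_depth=kw.pop("alt_depth", 40), **kw,
    )


def mnp(start, ref, alt, sample="BS1", chrom="chr1", caller="mutect2"):
    vtype = {2: "DNP", 3: "TNP"}.get(len(ref), "ONP")
    return VariantRecord(
        sample_id=sample, chrom=chrom, start=start, end=start + len(ref) - 1,
        ref=ref, alt=alt, variant_type=vtype, callers=frozenset({caller}),
        t_depth=100, alt_depth=40,
    )


class TestReconstructMnp:
    def test_full_support_merges_to_single_mnp(self):
        strelka = [snp(100, "C", "A"), snp(101, "G", "T")]
        out = reconstruct_mnp(strelka, [mnp(100, "CG", "AT")])
        assert len(out) == 1
        rec = out[0]
        assert (rec.start, rec.end, rec.ref, rec.alt) == (100, 101, "CG", "AT")
        assert rec.variant_type == "DNP"
        assert rec.callers == frozenset({"strelka2"})

    def test_partial_support_passes_through(self):
        strelka = [snp(100, "C", "A")]
        out = reconstruct_mnp(strelka, [mnp(100, "CG", "AT")])
        assert out == strelka

    def test_no_candidate_leaves_adjacent_snps(self):
        strelka = [snp(100, "C", "A"), snp(101, "G", "T")]
        assert sorted(reconstruct_mnp(strelka, []), key=lambda r: r.start) == strelka

    def test_overlapping_candidates_longest_then_leftmost(self):
        strelka = [snp(100, "C", "A"), snp(101, "G", "T"), snp(102, "A", "C")]
        candidates = [mnp(101, "GA", "TC"), mnp(100, "CGA", "ATC")]
        out = reconstruct_mnp(strelka, candidates)
        assert len(out) == 1
        assert (out[0].start, out[0].ref) == (100, "CGA")

    def test_leftmost_wins_among_equal_length(self):
        strelka = [snp(100, "C", "A"), snp(101, "G", "T"), snp(102, "A", "C")]
        candidates = [mnp(101, "GA", "TC"), mnp(100, "CG", "AT")]
        out = sorted(reconstruct_mnp(strelka, candidates), key=lambda r: r.start)
        # the left DNP claims 100-101; the right candidate loses its first base
        assert [(r.start, r.ref) for r in out] == [(100, "CG"), (102, "A")]

    def test_base_count_conservation_random(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        for _ in range(1000):
            start = int(rng.integers(1, 10_000))
            length = int(rng.integers(2, 5))
            ref = "".join(bases[rng.integers(4)] for _ in range(length))
            alt = "".join(bases[(bases.index(b) + 1) % 4] for b in ref)
            full = rng.random() < 0.5
            n_snps = length if full else int(rng.integers(0, length))
            strelka = [
                snp(start + i, ref[i], alt[i]) for i in range(n_snps)
            ]
            before = sum(len(r.ref) for r in strelka)
            out = reconstruct_mnp(strelka, [mnp(start, ref, alt)])
            assert sum(len(r.ref) for r in out) == before


class TestCallConsensus:
    def test_two_callers_retained(self):
        per_caller = {
            "strelka2": [snp(100, "C", "A", caller="strelka2")],
            "mutect2": [snp(100, "C", "A", caller="mutect2")],
        }
        out = call_consensus(per_caller, THR)
        assert len(out) == 1
        assert out[0].consensus_reason == "multi_caller"
        assert out[0].record.callers == frozenset({"strelka2", "mutect2"})

    def test_hotspot_rescue_single_caller(self):
        out = call_consensus(
            {"lancet": [snp(100, "C", "A", caller="lancet", hotspot=True)]}, THR
        )
        assert len(out) == 1
        assert out[0].consensus_reason == "hotspot_rescue"

    def test_single_caller_non_hotspot_dropped(self):
        assert call_consensus({"vardict": [snp(100, "C", "A", caller="vardict")]}, THR) == []

    def test_depth_donor_priority(self):
        per_caller = {
            "vardict": [snp(100, "C", "A", caller="vardict", t_depth=10, alt_depth=5)],
            "strelka2": [snp(100, "C", "A", caller="strelka2", t_depth=99, alt_depth=33)],
        }
        out = call_consensus(per_caller, THR)
        assert out[0].record.t_depth == 99

    def test_monotonic_in_caller_support(self):
        base = {
            "strelka2": [snp(100, "C", "A", caller="strelka2")],
            "mutect2": [snp(100, "C", "A", caller="mutect2")],
        }
        kept = {cv.key for cv in call_consensus(base, THR)}
        base["lancet"] = [snp(100, "C", "A", caller="lancet")]
        kept_more = {cv.key for cv in call_consensus(base, THR)}
        assert kept <= kept_more

    def test_oracle_equivalence_on_random_cohort(self):
        cohort = random_snv_cohort(seed=5, n_variants=1500)
        out = call_consensus(cohort.per_caller, THR)
        assert {cv.key for cv in out} == cohort.expected_keys
        # no variant key appears twice
        keys = [cv.key for cv in out]
        assert len(keys) == len(set(keys))


class TestGermlineFilter:
    def cv(self, hotspot, n_depth, gnomad):
        rec = snp(100, "C", "A", hotspot=hotspot, n_depth=n_depth,
                  gnomad_af=gnomad, caller="strelka2")
        rec = rec.with_callers(frozenset({"strelka2", "mutect2"}))
        return ConsensusVariant(record=rec, consensus_reason="multi_caller")

    @pytest.mark.parametrize("n_depth", [6, 7, 8])
    @pytest.mark.parametrize("gnomad", [0.0009, 0.001, 0.0011, 0.01])
    @pytest.mark.parametrize("hotspot", [True, False])
    def test_boundary_grid_matches_predicate(self, n_depth, gnomad, hotspot):
        cv = self.cv(hotspot, n_depth, gnomad)
        kept = filter_germline_leakage([cv], THR)
        expected_removed = (not hotspot) and n_depth <= 7 and gnomad > 0.001
        assert (len(kept) == 0) == expected_removed

    def test_absent_fields_never_trigger_removal(self):
        assert filter_germline_leakage([self.cv(False, None, 0.5)], THR)
        assert filter_germline_leakage([self.cv(False, 3, None)], THR)


class TestTumorOnlyFilter:
    @pytest.mark.parametrize(
        "alt_depth,t_depth,kept",
        [(0, 50, False), (2, 3, False), (1, 4, True), (1, 3, False), (0, 3, False),
         (10, 100, True)],
    )
    def test_depth_boundaries(self, alt_depth, t_depth, kept):
        rec = snp(100, "C", "A", t_depth=t_depth, alt_depth=alt_depth)
        assert bool(filter_tumor_only([rec], THR)) == kept

    def test_absent_depths_retained(self):
        rec = snp(100, "C", "A", t_depth=None, alt_depth=None)
        assert filter_tumor_only([rec], THR) == [rec]


class TestRunConsensus:
    def test_mnp_reconstruction_feeds_consensus(self):
        per_caller = {
            "strelka2": [snp(100, "C", "A"), snp(101, "G", "T")],
            "mutect2": [mnp(100, "CG", "AT")],
        }
        out = run_consensus(per_caller, THR)
        assert len(out) == 1
        rec = out[0].record
        assert (rec.ref, rec.alt) == ("CG", "AT")
        assert rec.callers == frozenset({"strelka2", "mutect2"})
        assert out[0].mnp_members != ()
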