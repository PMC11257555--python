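"""TMB: MNV splitting, denominators, numerator filters, scaling."""

import numpy as np
import pytest

from pedcns.errors import PedcnsError
from pedcns.intervals import GenomicInterval, IntervalSet
from pedcns.model import VariantRecord
from pedcns.tmb import (
    FOCR_NONSYN_CLASSES,
    compute_tmb,
    coding_denominator,
    nonsyn_filter_focr,
    split_mnv,
)


def variant(pos, ref="C", alt="A", vclass="Missense_Mutation", vtype="SNP",
            sample="BS1", chrom="chr1"):
    return VariantRecord(
        sample_id=sample, chrom=chrom, start=pos, end=pos + len(ref) - 1,
        ref=ref, alt=alt, variant_class=vclass, variant_type=vtype,
        callers=frozenset({"strelka2", "mutect2"}),
    )


class TestSplitMnv:
    def test_dnp_splits_into_per_base_snvs(self):
        out = split_mnv([variant(100, "CG", "AT", vtype="DNP")])
        assert [(r.start, r.ref, r.alt) for r in out] == [(100, "C", "A"), (101, "G", "T")]
        assert all(r.variant_type == "SNP" for r in out)

    def test_redundant_split_product_deduplicated(self):
        out = split_mnv([variant(100, "CG", "AT", vtype="DNP"), variant(100)])
        assert len(out) == 2

    def test_pure_snvs_unchanged(self):
        recs = [variant(100), variant(200)]
        assert split_mnv(recs) == recs

    def test_base_count_conserved(self):
        rng = np.random.default_rng(2)
        recs = []
        for _ in range(300):
            length = int(rng.integers(1, 5))
            pos = int(rng.integers(1, 1_000_000)) * 10  # spaced, no dedup losses
            ref = "ACGT"[: length]
            alt = "TACG"[: length]
            vtype = {1: "SNP", 2: "DNP", 3: "TNP", 4: "ONP"}[length]
            recs.append(variant(pos, ref, alt, vtype=vtype))
        before = sum(len(r.ref) for r in recs)
        after = sum(len(r.ref) for r in split_mnv(recs))
        assert after == before


class TestDenominators:
    def test_coding_denominator_example(self):
        surveyed = IntervalSet([GenomicInterval("chr1", 0, 1_000_000)])
        cds = IntervalSet([GenomicInterval("chr1", 400_000, 600_000)])
        assert coding_denominator(surveyed, cds) == 200_000

    def test_disjoint_sets_error(self):
        surveyed = IntervalSet([GenomicInterval("chr1", 0, 100)])
        cds = IntervalSet([GenomicInterval("chr2", 0, 100)])
        with pytest.raises(PedcnsError):
            coding_denominator(surveyed, cds)

    def test_random_sets_match_per_bp_oracle(self):
        rng = np.random.default_rng(8)
        size = 10_000
        mask_a = np.zeros(size, dtype=bool)
        mask_b = np.zeros(size, dtype=bool)
        ia, ib = [], []
        for _ in range(30):
            s, l = int(rng.integers(0, size - 10)), int(rng.integers(1, 500))
            ia.append(GenomicInterval("chr1", s, min(size, s + l)))
            mask_a[s : s + l] = True
            s, l = int(rng.integers(0, size - 10)), int(rng.integers(1, 500))
            ib.append(GenomicInterval("chr1", s, min(size, s + l)))
            mask_b[s : s + l] = True
        assert coding_denominator(IntervalSet(ia), IntervalSet(ib)) == int(
            (mask_a & mask_b).sum()
        )


class TestComputeTmb:
    ALL = IntervalSet([GenomicInterval("chr1", 0, 4_000_000)])
    CODING = IntervalSet([GenomicInterval("chr1", 0, 2_000_000)])

    def test_hand_example_six_per_mb(self):
        # 12 coding nonsynonymous mutations over a 2 Mb coding denominator
        recs = [variant(1000 + i * 10) for i in range(12)]
        result = compute_tmb(recs, "WGS", self.ALL, self.CODING)[0]
        assert result.tmb_coding == pytest.approx(6.0)
        assert result.numerator_coding == 12

    def test_zero_mutations(self):
        recs = [variant(1000)]
        results = compute_tmb(recs, "WGS", self.ALL, self.CODING)
        empty = compute_tmb([], "WGS", self.ALL, self.CODING)
        assert empty == []
        assert results[0].numerator_all == 1

    def test_silent_counts_in_all_not_coding(self):
        recs = [variant(1000, vclass="Silent")]
        result = compute_tmb(recs, "WGS", self.ALL, self.CODING)[0]
        assert result.numerator_all == 1
        assert result.numerator_coding == 0

    def test_variant_outside_denominator_excluded(self):
        recs = [variant(5_000_000)]
        result = compute_tmb(recs, "WGS", self.ALL, self.CODING)[0]
        assert result.numerator_all == 0

    def test_coding_numerator_bounded_by_all(self):
        rng = np.random.default_rng(4)
        recs = [
            variant(
                int(rng.integers(1, 4_000_000)),
                vclass=rng.choice(["Missense_Mutation", "Silent", "Nonsense_Mutation"]),
            )
            for _ in range(200)
        ]
        result = compute_tmb(recs, "WGS", self.ALL, self.CODING)[0]
        assert result.numerator_coding <= result.numerator_all

    def test_doubling_denominator_halves_tmb(self):
        recs = [variant(1000 + i) for i in range(10)]
        half = compute_tmb(recs, "WGS", self.ALL, self.CODING)[0]
        double = compute_tmb(
            recs,
            "WGS",
            IntervalSet([GenomicInterval("chr1", 0, 8_000_000)]),
            IntervalSet([GenomicInterval("chr1", 0, 4_000_000)]),
        )[0]
        assert double.tmb_all == pytest.approx(half.tmb_all / 2)
        assert double.tmb_coding == pytest.approx(half.tmb_coding / 2)


class TestFocrFilter:
    def test_membership_filter(self):
        recs = [
            variant(100, vclass="Missense_Mutation"),
            variant(200, vclass="Translation_Start_Site"),
            variant(300, vclass="Silent"),
        ]
        out = nonsyn_filter_focr(recs)
        assert [r.variant_class for r in out] == ["Missense_Mutation"]
        assert "Translation_Start_Site" not in FOCR_NONSYN_CLASSES
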