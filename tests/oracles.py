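"""Shared brute-force oracles, independent of the code paths they check."""

from pedcns.model import Thresholds


def brute_force_cnv_consensus(per_caller, thr=Thresholds()):
    """O(n^2) all-pairs restatement of the two CNV consensus rules.

    Returns a set of (sample, (chrom, start, end), direction, supporters).
    """
    expected = set()
    callers = sorted(per_caller)
    for i in range(len(callers)):
        for j in range(i + 1, len(callers)):
            for a in per_caller[callers[i]]:
                for b in per_caller[callers[j]]:
                    if a.sample_id != b.sample_id or a.direction != b.direction:
                        continue
                    if a.direction is None:
                        continue
                    if a.interval.chrom != b.interval.chrom:
                        continue
                    ov = min(a.interval.end, b.interval.end) - max(
                        a.interval.start, b.interval.start
                    )
                    if ov <= 0:
                        continue
                    fa = ov / a.interval.length
                    fb = ov / b.interval.length
                    sup = frozenset({callers[i], callers[j]})
                    if fa >= thr.recip_overlap and fb >= thr.recip_overlap:
                        iv = (
                            a.interval.chrom,
                            max(a.interval.start, b.interval.start),
                            min(a.interval.end, b.interval.end),
                        )
                        expected.add((a.sample_id, iv, a.direction, sup))
                    else:
                        small = a if a.interval.length <= b.interval.length else b
                        if ov / small.interval.length > thr.containment:
                            iv = (
                                small.interval.chrom,
                                small.interval.start,
                                small.interval.end,
                            )
                            expected.add((a.sample_id, iv, a.direction, sup))
    return expected
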