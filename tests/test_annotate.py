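"""Annotation-level read integration, repeat masking, and ranking."""

import numpy as np
import pytest

from clipcircuit.annotate import (AnnotationSummary, class_median_ratio,
                                  mask_repeat_features, rank_annotations,
                                  sum_reads_over_annotation,
                                  summarize_annotations)
from clipcircuit.intervals import FeatureAnnotation, GenomicInterval
from clipcircuit.readsets import ReadSet


def feat(fid, pairs, fclass="lncRNA", strand="+", chrom="chr1", gene=None):
    return FeatureAnnotation(
        fid, gene or fid, fclass,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in pairs),
    )


class TestSumReads:
    def test_empty_readset(self):
        assert sum_reads_over_annotation(ReadSet([], [], [], []), feat("f", [(0, 100)])) == 0

    def test_strand_aware_overlap_count(self):
        # {[10,30)+ x3, [50,60)- x2} over feature [0,100)+ -> 3
        rs = ReadSet(
            ["chr1"] * 5, [10, 10, 10, 50, 50], [30, 30, 30, 60, 60],
            ["+", "+", "+", "-", "-"],
        )
        assert sum_reads_over_annotation(rs, feat("f", [(0, 100)])) == 3

    def test_read_spanning_two_features_counts_in_both(self):
        rs = ReadSet(["chr1"], [95, ], [115], ["+"])
        a = feat("a", [(0, 100)])
        b = feat("b", [(100, 200)])
        assert sum_reads_over_annotation(rs, a) == 1
        assert sum_reads_over_annotation(rs, b) == 1


class TestMaskRepeats:
    def repeats(self, pairs):
        return [feat("rep", pairs, fclass="rrna_repeat")]

    def test_feature_inside_repeat_is_dropped(self):
        out = mask_repeat_features([feat("f", [(10, 50)])], self.repeats([(0, 100)]))
        assert out == []

    def test_no_overlap_identity(self):
        f = feat("f", [(10, 50)])
        assert mask_repeat_features([f], self.repeats([(200, 300)])) == [f]

    def test_masking_is_monotone_in_read_totals(self, rng):
        for _ in range(25):
            f = feat("f", [(0, 300)])
            rep = self.repeats([tuple(sorted(rng.integers(0, 300, 2) + [0, 1]))])
            n = 60
            starts = rng.integers(0, 290, n)
            rs = ReadSet(["chr1"] * n, starts, starts + rng.integers(1, 40, n), ["+"] * n)
            masked = mask_repeat_features([f], rep)
            before = sum_reads_over_annotation(rs, f)
            after = sum(sum_reads_over_annotation(rs, m) for m in masked)
            assert after <= before

    def test_rejects_non_repeat_class(self):
        with pytest.raises(ValueError):
            mask_repeat_features([feat("f", [(0, 10)])], [feat("x", [(0, 5)])])


def summaries(entries):
    return [
        AnnotationSummary(fid, fid, "lncRNA", reads, length)
        for fid, reads, length in entries
    ]


class TestRankAnnotations:
    def test_hand_ranked_with_tie(self):
        table = rank_annotations(summaries([("A", 10, 100), ("B", 10, 100), ("C", 5, 100)]))
        assert table["feature_id"].tolist() == ["A", "B", "C"]
        assert table["rank"].tolist() == [1, 2, 3]
        assert table["percentile_top"].iloc[-1] == 100.0

    def test_single_positive_feature(self):
        table = rank_annotations(summaries([("A", 3, 50), ("B", 0, 50)]))
        assert len(table) == 1
        assert table["rank"].iloc[0] == 1
        assert table["percentile_top"].iloc[0] == 100.0

    def test_percentile_is_rank_over_positive_count(self, rng):
        """percentile_top = 100*rank/N over bound features only.

        At full scale the same formula puts rank 8 of 87,912 bound
        annotations in the top 100*8/87912 = 0.0091%.
        """
        entries = [(f"f{i}", int(r), 100) for i, r in enumerate(rng.poisson(3, 200))]
        table = rank_annotations(summaries(entries))
        n_positive = sum(1 for _, r, _ in entries if r > 0)
        assert len(table) == n_positive
        np.testing.assert_allclose(
            table["percentile_top"], 100.0 * table["rank"] / n_positive
        )
        assert round(100.0 * 8 / 87_912, 4) == 0.0091

    def test_tiebreak_by_density_then_id_is_deterministic(self):
        rows = summaries([("B", 10, 50), ("A", 10, 100), ("C", 10, 50)])
        t1 = rank_annotations(rows)
        t2 = rank_annotations(list(reversed(rows)))
        # density 0.2 (B, C) beats 0.1 (A); B before C lexicographically
        assert t1["feature_id"].tolist() == ["B", "C", "A"]
        assert t1["feature_id"].tolist() == t2["feature_id"].tolist()

    def test_empty_input(self):
        assert rank_annotations([]).empty


class TestClassMedianRatio:
    def mixed(self, a_reads, b_reads):
        out = [AnnotationSummary(f"a{i}", f"a{i}", "lncRNA", r, 100)
               for i, r in enumerate(a_reads)]
        out += [AnnotationSummary(f"b{i}", f"b{i}", "three_prime_utr", r, 100)
                for i, r in enumerate(b_reads)]
        return out

    def test_identical_distributions(self):
        s = self.mixed([2, 4, 6], [2, 4, 6])
        assert class_median_ratio(s, "lncRNA", "three_prime_utr") == 1.0

    def test_hand_computed_ratio(self):
        s = self.mixed([2, 4, 6], [10, 20, 30])
        assert class_median_ratio(s, "lncRNA", "three_prime_utr") == 5.0

    def test_zero_read_features_excluded_from_median(self):
        s = self.mixed([0, 0, 2, 4, 6], [10, 20, 30])
        assert class_median_ratio(s, "lncRNA", "three_prime_utr") == 5.0

    def test_recovers_planted_depth_difference(self, rng):
        """Simulated 8x per-class depth difference is recovered within sampling error."""
        n = 120
        feats, reads = [], []
        for i in range(n):
            lo = 2000 * i  # gap > read length so reads never bleed across features
            feats.append(feat(f"l{i}", [(lo, lo + 500)], fclass="lncRNA"))
            feats.append(feat(f"u{i}", [(lo + 1000, lo + 1500)], fclass="three_prime_utr"))
        for f in feats:
            lam = 10 if f.feature_class == "lncRNA" else 80
            k = rng.poisson(lam)
            s = rng.integers(f.blocks[0].start, f.blocks[0].end - 1, k)
            reads.extend(zip(["chr1"] * k, s, s + 30, ["+"] * k))
        rs = ReadSet(*map(list, zip(*reads)))
        ratio = class_median_ratio(
            summarize_annotations(rs, feats), "lncRNA", "three_prime_utr"
        )
        assert 6.5 < ratio < 9.5

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            class_median_ratio(self.mixed([1], []), "lncRNA", "three_prime_utr")
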