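from __future__ import annotations

import numpy as np
import pytest

from mirloci import (
    FoldWindow,
    LocusMetrics,
    ThresholdSet,
    abundance_metrics,
    avg_genome_hits,
    bp_per_nt,
    compute_aapd,
    evaluate_locus,
    five_prime_heterogeneity,
    opposite_arm_offset,
    parse_structure,
    same_arm_offset,
)
from mirloci.metrics import OPPOSITE_ARM_SENTINEL

from conftest import make_product, make_read
from oracles import aapd_oracle


class TestAapd:
    def test_coincident_antisense_is_zero(self):
        sense = [make_product([(100, 122, 50)], "+")]
        anti = [make_product([(100, 122, 10)], "-")]
        assert compute_aapd(sense, anti) == 0.0

    def test_shifted_antisense(self):
        sense = [make_product([(100, 122, 50)], "+")]
        anti = [make_product([(108, 130, 10)], "-")]
        assert compute_aapd(sense, anti) == 8.0

    def test_no_antisense_products_pass(self):
        assert compute_aapd([make_product([(0, 22, 5)])], []) == 0.0

    def test_non_overlapping_pairs_ignored(self):
        sense = [make_product([(100, 122, 50)], "+")]
        anti = [make_product([(200, 222, 10)], "-")]
        assert compute_aapd(sense, anti) == 0.0

    def test_minus_strand_locus_mirrored(self):
        sense = [make_product([(100, 122, 50)], "-")]
        anti = [make_product([(100, 122, 10)], "+")]
        assert compute_aapd(sense, anti, sense_strand="-") == 0.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            ns, na = int(rng.integers(1, 5)), int(rng.integers(0, 5))
            s_spans = [(int(s), int(s) + 22) for s in rng.integers(0, 80, ns)]
            a_spans = [(int(s), int(s) + 22) for s in rng.integers(0, 80, na)]
            sense = [make_product([(s, e, 5)], "+") for s, e in s_spans]
            anti = [make_product([(s, e, 2)], "-") for s, e in a_spans]
            assert compute_aapd(sense, anti) == pytest.approx(
                aapd_oracle(s_spans, a_spans)
            )


class TestFivePrimeHeterogeneity:
    def test_direct_formula(self):
        p = make_product([(100, 122, 10), (101, 122, 2)])
        assert five_prime_heterogeneity(p) == pytest.approx(10 / 12)

    def test_homogeneous(self):
        assert five_prime_heterogeneity(make_product([(5, 27, 9)])) == 1.0

    def test_tie_resolved_then_half(self):
        p = make_product([(100, 122, 5), (101, 123, 5)])
        assert five_prime_heterogeneity(p) == 0.5

    def test_invariant_under_count_scaling(self):
        p1 = make_product([(100, 122, 10), (101, 122, 2), (102, 124, 3)])
        p2 = make_product([(100, 122, 40), (101, 122, 8), (102, 124, 12)])
        assert five_prime_heterogeneity(p1) == five_prime_heterogeneity(p2)

    def test_minus_strand_uses_three_prime_coordinate_end(self):
        # on '-', the 5' end is the genomic end; variants sharing it count
        p = make_product([(100, 122, 6), (98, 122, 3), (101, 121, 1)], "-")
        assert five_prime_heterogeneity(p) == pytest.approx(9 / 10)


class TestBpPerNt:
    def _window(self, n):
        return FoldWindow("chr1", 0, n, "+")

    def test_perfect_stem_product(self):
        s = "(" * 22 + "." * 4 + ")" * 22
        db = parse_structure("A" * 48, s)
        p = make_product([(0, 22, 5)])
        assert bp_per_nt(p, db.pair_table, self._window(48)) == 1.0

    def test_internal_bulge(self):
        s = "(" * 10 + "...." + "(" * 8 + "...." + ")" * 18
        db = parse_structure("A" * 44, s)
        p = make_product([(0, 22, 5)])
        assert bp_per_nt(p, db.pair_table, self._window(44)) == pytest.approx(18 / 22)

    def test_loop_product_zero(self):
        s = "(" * 5 + "." * 10 + ")" * 5
        db = parse_structure("A" * 20, s)
        p = make_product([(5, 15, 2)])
        assert bp_per_nt(p, db.pair_table, self._window(20)) == 0.0

    def test_product_outside_window_zero(self):
        db = parse_structure("AAAA", "....")
        p = make_product([(100, 122, 2)])
        assert bp_per_nt(p, db.pair_table, self._window(4)) == 0.0


class TestSameArmOffset:
    def test_one_nt_overlap_not_qualifying(self):
        ps = [make_product([(100, 122, 5)]), make_product([(121, 143, 5)])]
        assert same_arm_offset(ps) == 0

    def test_pairwise_offset(self):
        ps = [make_product([(100, 122, 5)]), make_product([(104, 126, 5)])]
        assert same_arm_offset(ps) == 4

    def test_single_product_vacuous(self):
        assert same_arm_offset([make_product([(100, 122, 5)])]) == 0

    def test_worst_case_over_pairs(self):
        ps = [
            make_product([(100, 122, 5)]),
            make_product([(102, 124, 5)]),
            make_product([(106, 128, 5)]),
        ]
        assert same_arm_offset(ps) == 6


class TestOppositeArmOffset:
    def _stem(self):
        # perfect 30-bp stem, loop 6: pairs (i, 65 - i)
        s = "(" * 30 + "." * 6 + ")" * 30
        return parse_structure("A" * 66, s), FoldWindow("chr1", 0, 66, "+")

    def test_canonical_two_nt_overhang(self):
        db, w = self._stem()
        fivep = make_product([(4, 26, 50)])
        # partners of the 3p span [38, 60) are {6..27}
        threep = make_product([(38, 60, 5)])
        assert opposite_arm_offset(fivep, threep, db.pair_table, w) == 2

    def test_exactly_complementary_zero(self):
        db, w = self._stem()
        fivep = make_product([(4, 26, 50)])
        threep = make_product([(40, 62, 5)])  # partners {4..25}
        assert opposite_arm_offset(fivep, threep, db.pair_table, w) == 0

    def test_disjoint_projection_sentinel(self):
        db, w = self._stem()
        fivep = make_product([(0, 4, 50)])
        threep = make_product([(36, 40, 5)])  # partners {26..29}
        assert (
            opposite_arm_offset(fivep, threep, db.pair_table, w)
            == OPPOSITE_ARM_SENTINEL
        )


class TestAbundance:
    def _mir(self, spans_counts):
        p = make_product(spans_counts)
        p.label = "5p-miR"
        return p

    def test_ppm_formula(self):
        total, ppm, top, distinct = abundance_metrics(
            [self._mir([(0, 22, 5)])], 1_000_000
        )
        assert (total, ppm, top, distinct) == (5, 5.0, 5, 1)

    def test_totals_sense_only_and_max_over_mirs(self):
        loop = make_product([(30, 40, 3)])
        loop.label = "loop"
        total, ppm, top, distinct = abundance_metrics(
            [self._mir([(0, 22, 8), (1, 23, 2)]), loop], 1000
        )
        assert total == 13 and top == 10 and distinct == 2
        assert ppm == pytest.approx(13000.0)

    def test_no_mir_product(self):
        loop = make_product([(30, 40, 3)])
        loop.label = "loop"
        assert abundance_metrics([loop], 1000)[2:] == (0, 0)


class TestAvgGenomeHits:
    def test_unique_reads(self):
        p = make_product([(0, 22, 5)])
        assert avg_genome_hits(p) == 1.0

    def test_weighted_mean(self):
        from mirloci import Product

        p = Product(strand="+", reads=[
            make_read(0, 22, count=8, hits=1),
            make_read(1, 23, count=2, hits=4),
        ])
        assert avg_genome_hits(p) == pytest.approx(1.6)


def perfect_metrics(**over):
    base = dict(
        hairpin_length=66,
        total_locus_reads=100,
        locus_ppm=50.0,
        max_product_reads=90,
        max_product_distinct=3,
        aapd=0.0,
        five_prime_het=0.9,
        min_bp_per_nt=0.9,
        mir_mor_distance=1,
        same_arm_offset=0,
        opposite_arm_offset=2,
        avg_genome_hits=1.0,
        non_mir_neighbor_count=None,
    )
    base.update(over)
    return LocusMetrics(**base)


class TestEvaluateLocus:
    def test_perfect_locus_positive(self):
        assert evaluate_locus(perfect_metrics()) == ("positive", [])

    @pytest.mark.parametrize(
        "override,reason",
        [
            ({"hairpin_length": 19}, "hairpin_too_short"),
            ({"hairpin_length": None}, "no_hairpin"),
            ({"total_locus_reads": 4}, "few_reads"),
            ({"locus_ppm": 0.5}, "low_ppm"),
            ({"max_product_reads": 1}, "top_product_single_read"),
            ({"max_product_reads": 0}, "no_mir_product"),
            ({"five_prime_het": 0.2}, "five_prime_heterogeneity"),
            ({"min_bp_per_nt": 0.4}, "low_pairing"),
            ({"same_arm_offset": 4}, "same_arm_offset"),
            ({"opposite_arm_offset": 6}, "opposite_arm_offset"),
            ({"mir_mor_distance": 6}, "mir_mor_gap"),
            ({"aapd": 8.0}, "antisense_displacement"),
            ({"avg_genome_hits": 2.5}, "repeat_like"),
            ({"non_mir_neighbor_count": 11}, "neighbor_count"),
        ],
    )
    def test_each_filter_fires(self, override, reason):
        verdict, reasons = evaluate_locus(perfect_metrics(**override))
        assert verdict == "rejected" and reasons == [reason]

    def test_all_failures_reported(self):
        verdict, reasons = evaluate_locus(
            perfect_metrics(hairpin_length=10, aapd=9.0, total_locus_reads=1)
        )
        assert verdict == "rejected"
        assert set(reasons) >= {"hairpin_too_short", "antisense_displacement", "few_reads"}

    def test_absent_optional_metrics_pass(self):
        m = perfect_metrics(
            mir_mor_distance=None, opposite_arm_offset=None, five_prime_het=None
        )
        assert evaluate_locus(m)[0] == "positive"

    def test_tightening_never_flips_rejected_to_positive(self):
        rng = np.random.default_rng(3)
        thr = ThresholdSet()
        for _ in range(300):
            m = perfect_metrics(
                hairpin_length=int(rng.integers(10, 80)),
                total_locus_reads=int(rng.integers(1, 20)),
                locus_ppm=float(rng.uniform(0, 5)),
                max_product_reads=int(rng.integers(0, 10)),
                aapd=float(rng.uniform(0, 4)),
                five_prime_het=float(rng.uniform(0, 1)),
                min_bp_per_nt=float(rng.uniform(0, 1)),
                same_arm_offset=int(rng.integers(0, 6)),
                opposite_arm_offset=int(rng.integers(0, 8)),
                avg_genome_hits=float(rng.uniform(1, 3)),
            )
            base = evaluate_locus(m, thr)[0]
            tight = ThresholdSet(min_locus_reads=thr.min_locus_reads + 2,
                                 max_aapd=0.0, min_bp_per_nt=0.8)
            if base == "rejected":
                assert evaluate_locus(m, tight)[0] == "rejected"
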