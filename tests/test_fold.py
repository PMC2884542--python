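from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirloci import (
    extract_hairpins,
    fold_baseline,
    fold_sequence,
    parse_structure,
    select_fold_windows,
)
from mirloci.fold import FoldWindow
from mirloci.regions import merge_reads_to_regions

from conftest import make_read
from oracles import max_pairs_exhaustive


class TestSelectFoldWindows:
    def _region(self, start, end, chrom="chr1"):
        (g,) = merge_reads_to_regions([make_read(start, end, chrom=chrom)])
        return g

    def _genome(self, length=100_000, chrom="chr1"):
        from mirloci import GenomeSequence

        return {chrom: GenomeSequence(chrom, "A" * length)}

    def test_three_windows_centered_and_anchored(self):
        reads = [make_read(1000, 1022)]
        (g,) = merge_reads_to_regions(reads)
        wins = select_fold_windows(g, self._genome(), 150)
        assert wins == [(936, 1086), (1000, 1150), (872, 1022)]

    def test_clipped_at_chromosome_start(self):
        wins = select_fold_windows(self._region(10, 32), self._genome(), 150)
        assert all(s >= 0 for s, _ in wins)
        assert (0, 150) in wins

    def test_region_equal_to_window_is_single(self):
        reads = [make_read(1000 + 30 * i, 1000 + 30 * i + 35) for i in range(5)]
        (g,) = merge_reads_to_regions(reads)
        assert g.length == 155  # > window below
        assert select_fold_windows(g, self._genome(), 150) == [(1000, 1155)]


class TestFoldBaseline:
    def test_simple_stem(self):
        db = fold_baseline("GGGAAAACCC")
        assert db.structure == "(((....)))" and db.n_pairs == 3

    def test_no_canonical_pairs(self):
        assert fold_baseline("AAAAAA").structure == "......"

    def test_n_bases_never_pair(self):
        assert fold_baseline("NNNAAAANNN").n_pairs == 0

    def test_deterministic_tiebreak_leftmost_outermost(self):
        db1 = fold_baseline("GCGCAAAAGCGC")
        db2 = fold_baseline("GCGCAAAAGCGC")
        assert db1.structure == db2.structure

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=12))
    def test_pair_count_matches_exhaustive_enumeration(self, seq):
        assert fold_baseline(seq).n_pairs == max_pairs_exhaustive(seq)

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=25))
    def test_structural_contract(self, seq):
        db = fold_baseline(seq)
        assert len(db.structure) == len(db.seq) == len(seq)
        # parse_structure validates balance and rebuilds the same pair table
        assert parse_structure(seq, db.structure).pair_table == db.pair_table


class TestEngines:
    def test_vienna_engine_agrees_on_perfect_stem(self):
        pytest.importorskip("RNA")
        seq = "G" * 12 + "AAAA" + "C" * 12
        db = fold_sequence(seq, engine="vienna")
        assert db.n_pairs >= 10 and db.energy is not None

    def test_callable_engine(self):
        db = fold_sequence("ACGT", engine=lambda s: "....")
        assert db.structure == "...."

    def test_unknown_engine_errors(self):
        with pytest.raises(ValueError, match="unknown folding engine"):
            fold_sequence("ACGT", engine="nope")

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            fold_sequence("", engine="baseline")


@st.composite
def balanced_structures(draw, max_len=40):
    """Random balanced dot-bracket strings built by recursive nesting."""
    def build(depth):
        parts = []
        for _ in range(draw(st.integers(0, 3))):
            choice = draw(st.integers(0, 2 if depth < 3 else 1))
            if choice == 2:
                parts.append("(" + build(depth + 1) + ")")
            else:
                parts.append("." * draw(st.integers(1, 4)))
        return "".join(parts)

    s = build(0)
    return s[:max_len] if s.count("(") == s[:max_len].count("(") else s


class TestParseStructure:
    def test_rejects_unbalanced(self):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_structure("ACGTA", "((..)")
        with pytest.raises(ValueError, match="unbalanced"):
            parse_structure("ACGTA", "(..))")

    @settings(max_examples=80, deadline=None)
    @given(balanced_structures())
    def test_accepts_any_balanced_string(self, structure):
        db = parse_structure("A" * len(structure), structure)
        for i, j in enumerate(db.pair_table):
            if j is not None:
                assert db.pair_table[j] == i


class TestExtractHairpins:
    def test_single_stem(self):
        db = parse_structure("A" * 12, "((((....))))")
        (hp,) = extract_hairpins(db)
        assert hp.loop == (4, 8) and hp.n_pairs == 4 and hp.hairpin_length == 12
        assert hp.fivep_arm == (0, 4) and hp.threep_arm == (8, 12)
        assert hp.too_short

    def test_no_pairs_no_hairpins(self):
        assert extract_hairpins(parse_structure("AAAA", "....")) == []

    def test_two_separate_stems(self):
        db = parse_structure("A" * 12, "((..))((..))")
        hps = extract_hairpins(db)
        assert len(hps) == 2
        assert hps[0].span == (0, 6) and hps[1].span == (6, 12)

    def test_bulged_stem_single_hairpin(self):
        db = parse_structure("A" * 16, "(((..((....)))))")
        (hp,) = extract_hairpins(db)
        assert hp.hairpin_length == 16 and hp.loop == (7, 11)

    def test_double_loop_merged_under_common_helix(self):
        s = "((((..((....))..((....))..))))"
        db = parse_structure("A" * len(s), s)
        (hp,) = extract_hairpins(db, merge_gap=8)
        assert hp.span == (0, 30)
        assert hp.loop == (8, 22)  # first loop start .. second loop end
        assert hp.fivep_arm == (0, 8) and hp.threep_arm == (22, 30)

    def test_double_loop_not_merged_when_gap_too_wide(self):
        s = "((((..((....))..((....))..))))"
        db = parse_structure("A" * len(s), s)
        assert len(extract_hairpins(db, merge_gap=1)) == 2

    def test_adjacent_stems_without_common_helix_not_merged(self):
        s = "((....))..((....))"
        db = parse_structure("A" * len(s), s)
        assert len(extract_hairpins(db, merge_gap=8)) == 2

    def test_spans_disjoint_and_ordered(self):
        s = "..((((....))))...((..((...))..))."
        db = parse_structure("A" * len(s), s)
        hps = extract_hairpins(db)
        spans = [hp.span for hp in hps]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_refolding_hairpin_subsequence_loses_no_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            db = fold_baseline(seq)
            for hp in extract_hairpins(db):
                s, e = hp.span
                sub = fold_baseline(seq[s:e])
                inside = sum(
                    1 for i in range(s, e)
                    if db.pair_table[i] is not None and s <= db.pair_table[i] < e and db.pair_table[i] > i
                )
                assert sub.n_pairs >= inside
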