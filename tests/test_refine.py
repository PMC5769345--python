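import pytest

from seqpan.datamodel import aligned_pairs, extract_genome_sequence, validate_alignment
from seqpan.pairwise import Scoring, score_alignment
from seqpan.refine import (
    find_consecutive_gap_sites,
    merge_short_single_blocks,
    realign_sites,
)

from conftest import block, entry, make_alignment, oracle_global_score, random_seq


class TestMerge:
    def _fixture(self):
        return make_alignment(
            [block(entry(1, 1, 3, "+", "ACT"), entry(2, 1, 3, "+", "AGT")),
             block(entry(1, 4, 5, "+", "GG"), tag="single_sequence"),
             block(entry(1, 6, 9, "+", "TTTT"), entry(2, 4, 7, "+", "TTTT"))],
            {1: 9, 2: 7})

    def test_short_single_block_appended_with_padding(self):
        out = merge_short_single_blocks(self._fixture(), max_len=10)
        assert len(out.blocks) == 2
        first = out.blocks[0]
        assert first.entry(1).text == "ACTGG"
        assert first.entry(2).text == "AGT--"
        assert first.entry(1).end == 5
        assert validate_alignment(out) == []

    def test_pairs_and_sequences_unchanged(self):
        a = self._fixture()
        out = merge_short_single_blocks(a, max_len=10)
        assert aligned_pairs(out) == aligned_pairs(a)
        for gid in (1, 2):
            assert extract_genome_sequence(out, gid) == \
                extract_genome_sequence(a, gid)

    def test_block_without_contiguous_neighbour_untouched(self):
        a = make_alignment(
            [block(entry(1, 1, 2, "+", "AC"), tag="single_sequence"),
             block(entry(2, 1, 4, "+", "ACGT"), tag="single_sequence")],
            {1: 2, 2: 4})
        out = merge_short_single_blocks(a, max_len=10)
        assert len(out.blocks) == 2

    def test_long_single_blocks_kept(self):
        a = self._fixture()
        out = merge_short_single_blocks(a, max_len=1)
        assert len(out.blocks) == 3

    def test_merge_into_reverse_strand_neighbour(self):
        a = make_alignment(
            [block(entry(1, 4, 7, "-", "TGCA"), entry(2, 1, 4, "+", "TGCA")),
             block(entry(1, 1, 3, "+", "GGG"), tag="single_sequence"),
             block(entry(2, 5, 7, "+", "AAA"), tag="single_sequence")],
            {1: 7, 2: 7})
        out = merge_short_single_blocks(a, max_len=10)
        merged = out.blocks[0]
        # forward start 1-3 attaches after the "-" row's text as revcomp
        assert merged.entry(1).text.startswith("TGCACCC")
        assert merged.entry(1).start == 1
        assert extract_genome_sequence(out, 1) == \
            extract_genome_sequence(a, 1)
        assert validate_alignment(out) == []


class TestConsecutiveGapSites:
    def test_basic_site(self):
        b = block(entry(1, 1, 6, "+", "AAA---CCC"), entry(2, 1, 6, "+", "AAACCC---"))
        sites = find_consecutive_gap_sites(b)
        assert [(s.start_col, s.end_col) for s in sites] == [(4, 9)]

    def test_single_column_runs(self):
        b = block(entry(1, 1, 2, "+", "A-A"), entry(2, 1, 2, "+", "AA-"))
        assert [(s.start_col, s.end_col) for s in find_consecutive_gap_sites(b)] == \
            [(2, 3)]

    def test_gaps_in_one_row_only(self):
        b = block(entry(1, 1, 4, "+", "AC-GT"), entry(2, 1, 5, "+", "ACCGT"))
        assert find_consecutive_gap_sites(b) == []

    def test_non_adjacent_runs_are_not_sites(self):
        b = block(entry(1, 1, 7, "+", "A--ACGTAA"[:9]), entry(2, 1, 7, "+", "AGGACGT--"))
        assert find_consecutive_gap_sites(b) == []


class TestRealign:
    def test_consecutive_gaps_collapse(self):
        a = make_alignment(
            [block(entry(1, 1, 6, "+", "AAA---CCC"), entry(2, 1, 6, "+", "AAACCC---"))],
            {1: 6, 2: 6})
        out = realign_sites(a)
        blk = out.blocks[0]
        assert blk.length == 6
        assert blk.entry(1).text == "AAACCC"
        assert blk.entry(2).text == "AAACCC"

    def test_idempotent_on_optimal_alignment(self):
        a = make_alignment(
            [block(entry(1, 1, 6, "+", "AAACCC"), entry(2, 1, 6, "+", "AAACCC"))],
            {1: 6, 2: 6})
        out = realign_sites(a)
        assert out.blocks[0].entry(1).text == "AAACCC"

    def test_sequences_conserved_and_score_monotone(self, rng):
        scoring = Scoring()
        for _ in range(25):
            # random two-row block with a manufactured consecutive-gap site
            n = int(rng.integers(20, 80))
            s1 = random_seq(rng, n)
            s2 = random_seq(rng, n)
            g = int(rng.integers(1, 8))
            p = int(rng.integers(5, n - 10))
            t1 = s1[:p] + "-" * g + s1[p:]
            t2 = s2[:p + g] + "-" * g + s2[p + g - g:][:len(t1) - p - g]
            t2 = (s2 + "-" * g)[:len(t1)]
            t1 = (s1[:p] + "-" * g + s1[p:])[:len(t2)]
            n1, n2 = len(t1.replace("-", "")), len(t2.replace("-", ""))
            a = make_alignment(
                [block(entry(1, 1, n1, "+", t1), entry(2, 1, n2, "+", t2))],
                {1: n1, 2: n2})
            if validate_alignment(a):
                continue
            out = realign_sites(a)
            blk = out.blocks[0]
            assert blk.entry(1).text.replace("-", "") == t1.replace("-", "")
            assert blk.entry(2).text.replace("-", "") == t2.replace("-", "")
            assert score_alignment(blk.entry(1).text, blk.entry(2).text, scoring) >= \
                score_alignment(t1, t2, scoring)

    def test_realigned_interval_is_globally_optimal(self, rng):
        # on small blocks the whole block is one extended interval, so the
        # result must reach the independent oracle's optimal score
        for _ in range(10):
            s = random_seq(rng, 60)
            s2 = s[:20] + s[26:]
            t1 = s
            t2 = s2[:20] + "------" + s2[20:]
            a = make_alignment(
                [block(entry(1, 1, 60, "+", t1 + "---"),
                       entry(2, 1, 57, "+", "---" + t2))],
                {1: 60, 2: 54})
            if validate_alignment(a):
                continue
            out = realign_sites(a)
            blk = out.blocks[0]
            assert score_alignment(blk.entry(1).text, blk.entry(2).text) == \
                oracle_global_score(t1.replace("-", ""), t2.replace("-", ""))
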