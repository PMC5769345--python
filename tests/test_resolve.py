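import pytest

from seqpan.aligner import AlignerConfig, align_pair
from seqpan.consensus import build_consensus, consensus_identity_alignment
from seqpan.datamodel import (
    aligned_pairs,
    extract_genome_sequence,
    validate_alignment,
)
from seqpan.genome_ops import WorkflowConfig, add_genome, build_pan, initial_pan, remove_genome
from seqpan.resolve import SuperSequence, align_leftovers, reconstruct, split_at_delimiters
from seqpan.simulate import MutationModel, simulate_genomes

from conftest import block, entry, make_alignment, random_seq


class TestSuperSequence:
    def test_build_and_map(self):
        sup = SuperSequence.build([("ACGT", 11), ("GGCC", 31)], 10)
        assert sup.sequence == "ACGT" + "N" * 10 + "GGCC"
        assert sup.delimiters == [(5, 10)]
        assert sup.map_interval(1, 4) == (11, 14)
        assert sup.map_interval(15, 16) == (31, 32)

    def test_crossing_interval_rejected(self):
        sup = SuperSequence.build([("ACGT", 1), ("GGCC", 10)], 5)
        with pytest.raises(Exception):
            sup.map_interval(3, 11)


class TestSplitAtDelimiters:
    def test_three_way_split(self, rng):
        # a block spanning a complete delimiter yields three blocks; the
        # middle keeps only the new genome with its gaps removed
        left = random_seq(rng, 5)
        right = random_seq(rng, 7)
        mid_new = random_seq(rng, 1000)
        cons_text = left + "N" * 1000 + right
        new_text = left + mid_new[:998] + "--" + mid_new[998:] + right
        cons_gapped = cons_text[:5 + 998] + "--" + cons_text[5 + 998:]
        a = make_alignment(
            [block(entry(1, 1, 1012, "+", cons_gapped),
                   entry(2, 1, 1012, "+", new_text))],
            {1: 1012, 2: 1012})
        out = split_at_delimiters(a, [(6, 1000)], target_genome_id=1)
        assert len(out.blocks) == 3
        first, middle, last = out.blocks
        assert first.entry(1).end == 5 and first.length == 5
        assert middle.genome_ids() == [2]
        assert "-" not in middle.entries[0].text
        assert middle.length == 1000
        assert last.entry(1).start == 1006 and last.length == 7

    def test_delimiter_matched_by_gaps_only_discarded(self, rng):
        seq = random_seq(rng, 10)
        cons_text = seq[:5] + "N" * 20 + seq[5:]
        new_text = seq[:5] + "-" * 20 + seq[5:]
        a = make_alignment(
            [block(entry(1, 1, 30, "+", cons_text), entry(2, 1, 10, "+", new_text))],
            {1: 30, 2: 10})
        out = split_at_delimiters(a, [(6, 20)], target_genome_id=1)
        assert len(out.blocks) == 2
        assert all("N" not in b.entry(1).text for b in out.blocks)

    def test_block_inside_one_consensus_block_unchanged(self, rng):
        seq = random_seq(rng, 40)
        a = make_alignment(
            [block(entry(1, 1, 40, "+", seq), entry(2, 1, 40, "+", seq))],
            {1: 40, 2: 40})
        out = split_at_delimiters(a, [(100, 50)], target_genome_id=1)
        assert len(out.blocks) == 1 and out.blocks[0].length == 40


class TestAlignLeftovers:
    def test_no_single_blocks_is_identity(self, rng):
        seq = random_seq(rng, 60)
        a = make_alignment(
            [block(entry(1, 1, 60, "+", seq), entry(2, 1, 60, "+", seq))],
            {1: 60, 2: 60})
        out = align_leftovers(a, AlignerConfig(), 100)
        assert out is a

    def test_translocated_segment_recovered(self, rng):
        # a 300 bp segment unaligned in the first pass emerges as one
        # two-entry block after the leftover pass
        seg = random_seq(rng, 300)
        flank_a = random_seq(rng, 400)
        flank_b = random_seq(rng, 400)
        a = make_alignment(
            [block(entry(1, 1, 400, "+", flank_a), entry(2, 1, 400, "+", flank_a)),
             block(entry(1, 401, 700, "+", seg), tag="single_sequence"),
             block(entry(1, 701, 1100, "+", flank_b), entry(2, 701, 1100, "+", flank_b)),
             block(entry(2, 401, 700, "+", seg), tag="single_sequence")],
            {1: 1100, 2: 1100})
        out = align_leftovers(a, AlignerConfig(), 100)
        two_entry = [b for b in out.blocks if len(b.entries) == 2]
        assert len(two_entry) == 3
        recovered = [b for b in two_entry if b.entry(1).start == 401]
        assert len(recovered) == 1
        assert recovered[0].entry(2).start == 401
        pairs = aligned_pairs(out)
        assert all(((1, 400 + k), (2, 400 + k), "same") in set(pairs)
                   for k in range(1, 301))

    def test_unrelated_leftovers_stay_single(self, rng):
        shared = random_seq(rng, 300)
        a = make_alignment(
            [block(entry(1, 1, 300, "+", shared), entry(2, 1, 300, "+", shared)),
             block(entry(1, 301, 500, "+", random_seq(rng, 200)), tag="single_sequence"),
             block(entry(2, 301, 500, "+", random_seq(rng, 200)), tag="single_sequence")],
            {1: 500, 2: 500})
        out = align_leftovers(a, AlignerConfig(), 100)
        singles = [b for b in out.blocks if len(b.entries) == 1]
        assert sum(b.length for b in singles) >= 2 * 200 - 30  # mostly single


class TestReconstruct:
    def _pan(self, rng, n=3, length=6000, seed=2):
        model = MutationModel(seed=seed)
        genomes, _ = simulate_genomes(length, n, model)
        pan, c = build_pan([(f"g{i+1}", g) for i, g in enumerate(genomes)],
                           WorkflowConfig(), order="given")
        return pan, c

    def test_identity_overlay_reproduces_pairs(self, rng):
        pan, c = self._pan(rng)
        before = aligned_pairs(pan)
        rec = reconstruct(consensus_identity_alignment(c), c)
        assert validate_alignment(rec) == []
        n = len(pan.genomes)
        among_orig = remove_genome(rec, n + 1)
        assert aligned_pairs(among_orig) == before

    def test_new_rows_equal_block_consensuses(self, rng):
        pan, c = self._pan(rng, n=2, length=3000)
        rec = reconstruct(consensus_identity_alignment(c), c)
        new_gid = len(pan.genomes) + 1
        for row, blk in zip(c.index.block_table, pan.blocks):
            expected = c.sequence[row.cons_start - 1:row.cons_end]
            found = [b for b in rec.blocks
                     if b.entry(new_gid) is not None
                     and b.entry(new_gid).start == row.cons_start
                     and len(b.entries) > 1]
            assert found and found[0].entry(new_gid).text.replace("-", "") == expected

    def test_gap_columns_inserted_into_all_rows(self):
        # pairwise alignment adds a 2-gap run in the consensus row: every
        # original row gains "--" at those columns, pairs unchanged
        prev = make_alignment(
            [block(entry(1, 1, 6, "+", "ACGTAC"), entry(2, 1, 6, "+", "ACGTAC"))],
            {1: 6, 2: 6})
        c = build_consensus(prev)
        pairwise = make_alignment(
            [block(entry(1, 1, 6, "+", "ACG--TAC"), entry(2, 1, 8, "+", "ACGGGTAC"))],
            {1: 6, 2: 8})
        rec = reconstruct(pairwise, c)
        assert validate_alignment(rec) == []
        blk = rec.blocks[0]
        assert blk.entry(1).text == "ACG--TAC"
        assert blk.entry(2).text == "ACG--TAC"
        assert blk.entry(3).text == "ACGGGTAC"
        among = {((gi, pi), (gj, pj), o) for (gi, pi), (gj, pj), o in aligned_pairs(rec)
                 if gj <= 2}
        assert among == {((1, k), (2, k), "same") for k in range(1, 7)}

    def test_pair_preservation_when_adding_genome(self, rng):
        model = MutationModel(seed=8)
        genomes, _ = simulate_genomes(5000, 4, model)
        pan, c = build_pan([(f"g{i+1}", g) for i, g in enumerate(genomes[:3])],
                           WorkflowConfig(), order="given")
        before = aligned_pairs(pan)
        pan4, _ = add_genome(pan, c, genomes[3], name="g4", wf=WorkflowConfig())
        among_orig = {p for p in aligned_pairs(pan4) if p[1][0] <= 3}
        assert among_orig == set(before)

    def test_genomes_round_trip_through_workflow(self, rng):
        model = MutationModel(seed=13)
        genomes, _ = simulate_genomes(8000, 3, model)
        pan, c = build_pan([(f"g{i+1}", g) for i, g in enumerate(genomes)],
                           WorkflowConfig(), order="given")
        for gid, g in zip((1, 2, 3), genomes):
            assert extract_genome_sequence(pan, gid) == g
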