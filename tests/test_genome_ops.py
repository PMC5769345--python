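import numpy as np
import pytest

from seqpan.consensus import build_consensus, genome_pos_to_consensus
from seqpan.datamodel import (
    SeqPanError,
    aligned_pairs,
    extract_genome_sequence,
    validate_alignment,
)
from seqpan.genome_ops import (
    WorkflowConfig,
    add_genome,
    build_pan,
    initial_pan,
    map_position,
    order_genomes,
    remove_genome,
)
from seqpan.simulate import MutationModel, simulate_genomes

from conftest import block, entry, make_alignment, random_seq


def small_pan(seed=3, n=3, length=5000, **model_kw):
    model = MutationModel(seed=seed, max_deletion_length=500, **model_kw)
    genomes, truth = simulate_genomes(length, n, model)
    pan, c = build_pan([(f"g{i+1}", g) for i, g in enumerate(genomes)],
                       WorkflowConfig(), order="given")
    return genomes, pan, c


class TestAddGenome:
    def test_identical_genome_duplicates_rows(self, rng):
        g = random_seq(rng, 3000)
        pan, c = build_pan([("g1", g), ("g2", g)], WorkflowConfig(), order="given")
        pan3, _ = add_genome(pan, c, g, name="g3", wf=WorkflowConfig())
        assert all(len(b.entries) == 3 for b in pan3.blocks)
        assert extract_genome_sequence(pan3, 3) == g

    def test_consensus_with_substitutions_overlays_block_per_block(self, rng):
        genomes, pan, c = small_pan(n=2, length=4000,
                                    inversions=0, translocations=0,
                                    large_deletions=0, indel_rate=0)
        new = list(c.sequence)
        real = [i for i, ch in enumerate(new) if ch != "N"]
        for p in rng.choice(len(real), 10, replace=False):
            i = real[p]
            new[i] = "ACGT"[("ACGT".index(new[i]) + 1) % 4]
        new_seq = "".join(ch for ch in new if ch != "N")
        pan3, _ = add_genome(pan, c, new_seq, name="g3", wf=WorkflowConfig())
        assert validate_alignment(pan3) == []
        assert len([b for b in pan3.blocks if len(b.entries) == 1]) == 0

    def test_input_pan_untouched(self, rng):
        genomes, pan, c = small_pan()
        snapshot = aligned_pairs(pan)
        n_blocks = len(pan.blocks)
        add_genome(pan, c, genomes[0], name="again", wf=WorkflowConfig())
        assert len(pan.blocks) == n_blocks
        assert aligned_pairs(pan) == snapshot


class TestRemoveGenome:
    def test_remove_to_single_genome(self, rng):
        g = random_seq(rng, 2000)
        g2 = g[:900] + g[950:]
        pan, c = build_pan([("g1", g), ("g2", g2)], WorkflowConfig(), order="given")
        only = remove_genome(pan, 2)
        assert only.genome_ids() == [1]
        assert all("-" not in b.entries[0].text for b in only.blocks)
        assert extract_genome_sequence(only, 1) == g

    def test_allgap_columns_cut_and_blocks_joined(self):
        pan = make_alignment(
            [block(entry(1, 1, 3, "+", "ACG-"), entry(2, 1, 4, "+", "ACGT")),
             block(entry(1, 4, 6, "+", "TTT"), entry(2, 5, 7, "+", "TTT"))],
            {1: 6, 2: 7})
        out = remove_genome(pan, 2)
        assert len(out.blocks) == 1
        assert out.blocks[0].entries[0].text == "ACGTTT"

    def test_add_then_remove_is_identity_on_pairs(self):
        genomes, pan, c = small_pan(seed=17)
        before = aligned_pairs(pan)
        model = MutationModel(seed=99, max_deletion_length=300)
        extra, _ = simulate_genomes(5000, 1, model)
        pan4, _ = add_genome(pan, c, extra[0], name="gx", wf=WorkflowConfig())
        assert aligned_pairs(remove_genome(pan4, 4)) == before

    def test_remove_last_genome_rejected(self, rng):
        pan = initial_pan("g1", [("g1", random_seq(rng, 100))])
        with pytest.raises(SeqPanError):
            remove_genome(pan, 1)

    def test_unknown_genome_rejected(self, rng):
        pan = initial_pan("g1", [("g1", random_seq(rng, 100))])
        with pytest.raises(KeyError):
            remove_genome(pan, 5)


class TestMapPosition:
    def test_single_genome_pan_identity(self, rng):
        g = random_seq(rng, 500)
        pan = initial_pan("g1", [("g1", g)])
        c = build_consensus(pan)
        for pos in (1, 250, 500):
            res = map_position(c, 1, pos)
            assert res["consensus"] == pos  # single block: no delimiter shift
            assert res[1] == (pos, "+")

    def test_round_trip_on_all_nongap_sites(self):
        genomes, pan, c = small_pan(seed=23, n=3, length=3000)
        for gid in (1, 2, 3):
            L = pan.genome(gid).total_length
            for pos in range(1, L + 1, 11):
                res = map_position(c, gid, pos)
                assert res[gid] == (pos, res[gid][1])

    def test_inverted_block_counts_from_right_edge(self, rng):
        g = random_seq(rng, 800)
        text = g[100:300]
        pan = make_alignment(
            [block(entry(1, 1, 200, "+", text), entry(2, 601, 800, "-", text)),
             block(entry(2, 1, 600, "+", random_seq(rng, 600)), tag="single_sequence")],
            {1: 200, 2: 800})
        pan.blocks.sort(key=lambda b: b.entries[0].genome_id)
        c = build_consensus(pan)
        cp, strand = genome_pos_to_consensus(c, 2, 800)
        assert strand == "-"
        res = map_position(c, 2, 800)
        assert res[1][0] == 1  # forward end of the inversion pairs with start


class TestOrderGenomes:
    def test_dissimilarity_interleave(self, rng):
        # six genomes at increasing distance from the first
        base = random_seq(rng, 3000)
        seqs = [base]
        for i in range(1, 6):
            s = list(base)
            for p in rng.choice(3000, 120 * i, replace=False):
                s[p] = "ACGT"[int(rng.integers(0, 4))]
            seqs.append("".join(s))
        sim = order_genomes(seqs, "similarity")
        dis = order_genomes(seqs, "dissimilarity")
        assert dis == [sim[0], sim[5], sim[1], sim[4], sim[2], sim[3]]

    def test_identical_genomes_stable(self, rng):
        g = random_seq(rng, 1000)
        assert order_genomes([g, g, g], "similarity") == [0, 1, 2]

    def test_two_genomes_deterministic(self, rng):
        a, b = random_seq(rng, 800), random_seq(rng, 800)
        assert order_genomes([a, b], "similarity") == order_genomes([a, b], "similarity")

    def test_random_mode_seeded(self, rng):
        seqs = [random_seq(rng, 200) for _ in range(5)]
        assert order_genomes(seqs, "random", seed=4) == order_genomes(seqs, "random", seed=4)
        assert sorted(order_genomes(seqs, "random", seed=4)) == [0, 1, 2, 3, 4]


class TestBuildPan:
    def test_one_genome_trivial_pan(self, rng):
        g = random_seq(rng, 700)
        pan, c = build_pan([("g1", g)], WorkflowConfig())
        assert len(pan.blocks) == 1
        assert c.sequence == g.upper()

    def test_two_identical_genomes_single_block(self, rng):
        g = random_seq(rng, 1500)
        pan, c = build_pan([("g1", g), ("g2", g)], WorkflowConfig(), order="given")
        assert len(pan.blocks) == 1
        assert len(pan.blocks[0].entries) == 2

    def test_multi_replicon_round_trip(self, rng):
        chr1 = random_seq(rng, 2000)
        plasmid = random_seq(rng, 800)
        other = chr1[:1000] + plasmid[:400]
        pan, c = build_pan(
            [("gA", [("chr", chr1), ("p1", plasmid)]), ("gB", other)],
            WorkflowConfig(), order="given")
        assert validate_alignment(pan) == []
        assert extract_genome_sequence(pan, 1) == chr1 + plasmid
        assert pan.genome(1).replicons == [("chr", 2000), ("p1", 800)]
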