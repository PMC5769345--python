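"""Pan-genome lifecycle: sequential build, add, remove, coordinate mapping
and genome ordering.

``add_genome`` runs one full workflow iteration: pairwise alignment of the
consensus with the incoming genome, merging of short single-sequence
blocks, realignment of consecutive-gap sites, resolving at delimiter
borders, a leftover-alignment pass, reconstruction of the full alignment,
and a fresh consensus.  The input pan-genome is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    Block,
    GenomeAlignment,
    GenomeRecord,
    SeqPanError,
    SequenceEntry,
    remove_allgap_columns,
    require_valid,
)
from .aligner import AlignerConfig, align_pair
from .consensus import (
    DEFAULT_DELIMITER_LENGTH,
    ConsensusGenome,
    build_consensus,
    consensus_pos_to_genomes,
    genome_pos_to_consensus,
)
from .refine import merge_short_single_blocks, realign_sites
from .resolve import SuperSequence, align_leftovers, reconstruct, split_at_delimiters

Replicons = list[tuple[str, str]]  # (replicon_name, sequence)


@dataclass
class WorkflowConfig:
    """Workflow-level switches around one :class:`AlignerConfig`."""

    aligner: AlignerConfig
    merge: bool = True
    merge_max_len: int = 10
    realign: bool = True
    delimiter_length: int = DEFAULT_DELIMITER_LENGTH
    tie_policy: str = "lex"
    seed: int | None = None

    def __init__(self, aligner: AlignerConfig | None = None, merge: bool = True,
                 merge_max_len: int = 10, realign: bool = True,
                 delimiter_length: int = DEFAULT_DELIMITER_LENGTH,
                 tie_policy: str = "lex", seed: int | None = None):
        self.aligner = aligner or AlignerConfig()
        self.merge = merge
        self.merge_max_len = merge_max_len
        self.realign = realign
        self.delimiter_length = delimiter_length
        self.tie_policy = tie_policy
        self.seed = seed


def _as_replicons(g, name: str) -> Replicons:
    if isinstance(g, str):
        return [(name, g)]
    return list(g)


def add_genome(pan: GenomeAlignment, c: ConsensusGenome, g,
               name: str = "genome",
               wf: WorkflowConfig | None = None) -> tuple[GenomeAlignment, ConsensusGenome]:
    """Add one genome to a pan-genome; returns the new alignment and its
    consensus.  ``g`` is a sequence string or a list of (replicon, seq).
    """
    wf = wf or WorkflowConfig()
    replicons = _as_replicons(g, name)
    if c.source_alignment is None:
        c.source_alignment = pan

    super_g = None
    if len(replicons) == 1:
        g_seq = replicons[0][1]
    else:
        pieces = []
        offset = 0
        for _, seq in replicons:
            pieces.append((seq, offset + 1))
            offset += len(seq)
        super_g = SuperSequence.build(pieces, wf.delimiter_length)
        g_seq = super_g.sequence

    pw = align_pair(c.sequence, g_seq, wf.aligner,
                    name_a="consensus", name_b=name)
    if wf.merge:
        pw = merge_short_single_blocks(pw, wf.merge_max_len)
    if wf.realign:
        pw = realign_sites(pw, wf.aligner.scoring, wf.aligner.band_width)
    pw = split_at_delimiters(pw, c.index.delimiter_index, target_genome_id=1)
    if super_g is not None:
        pw = split_at_delimiters(pw, super_g.delimiters, target_genome_id=2)
        for block in pw.blocks:
            e = block.entry(2)
            if e is not None and not e.is_empty:
                e.start, e.end = super_g.map_interval(e.start, e.end)
    if wf.merge:
        pw = merge_short_single_blocks(pw, wf.merge_max_len)
    pw = align_leftovers(pw, wf.aligner, wf.delimiter_length,
                         merge=wf.merge, merge_max_len=wf.merge_max_len,
                         realign=wf.realign)
    # the leftover pass aligned super-sequences built from genome-global
    # coordinates, so replicon metadata must be attached afterwards
    pw.genomes[1] = GenomeRecord(
        2, name, [(rn, len(seq)) for rn, seq in replicons])

    full = reconstruct(pw, c)
    if wf.merge:
        full = merge_short_single_blocks(full, wf.merge_max_len)
    require_valid(full)
    c_new = build_consensus(full, wf.delimiter_length, wf.tie_policy, wf.seed)
    return full, c_new


def remove_genome(pan: GenomeAlignment, genome_id: int) -> GenomeAlignment:
    """Drop one genome: its rows disappear, columns gapped everywhere else
    are cut, empty blocks vanish, adjacent blocks over the same genome set
    with contiguous coordinates are joined, and ids are renumbered
    compactly."""
    pan.genome(genome_id)
    if len(pan.genomes) < 2:
        raise SeqPanError("cannot remove the last genome of a pan-genome")

    blocks: list[Block] = []
    for block in pan.blocks:
        kept = [e for e in block.entries if e.genome_id != genome_id]
        kept = [e for e in kept if not e.is_empty]
        if not kept:
            continue
        texts = remove_allgap_columns([e.text for e in kept])
        entries = [SequenceEntry(e.genome_id, e.start, e.end, e.strand, t)
                   for e, t in zip(kept, texts)]
        blocks.append(Block(
            entries, tag="single_sequence" if len(entries) == 1 else block.tag))

    def joinable(x: Block, y: Block) -> bool:
        if sorted(x.genome_ids()) != sorted(y.genome_ids()):
            return False
        for ex in x.entries:
            ey = y.entry(ex.genome_id)
            if ey.strand != ex.strand:
                return False
            if ex.strand == "+":
                if ex.end + 1 != ey.start:
                    return False
            else:
                if ex.start != ey.end + 1:
                    return False
        return True

    joined: list[Block] = []
    for block in blocks:
        if joined and joinable(joined[-1], block):
            prev = joined[-1]
            for ex in prev.entries:
                ey = block.entry(ex.genome_id)
                ex.text = ex.text + ey.text
                if ex.strand == "+":
                    ex.end = ey.end
                else:
                    ex.start = ey.start
        else:
            joined.append(block)

    old_ids = sorted(g.genome_id for g in pan.genomes if g.genome_id != genome_id)
    renum = {old: new for new, old in enumerate(old_ids, start=1)}
    genomes = [GenomeRecord(renum[g.genome_id], g.name, list(g.replicons))
               for g in pan.genomes if g.genome_id != genome_id]
    for block in joined:
        for e in block.entries:
            e.genome_id = renum[e.genome_id]
    out = GenomeAlignment(sorted(genomes, key=lambda g: g.genome_id), joined)
    require_valid(out)
    return out


def map_position(c: ConsensusGenome, from_genome: int, pos: int) -> dict:
    """Lift one position onto the consensus and every genome.

    ``from_genome == 0`` means ``pos`` is a consensus coordinate.  Returns
    ``{"consensus": int | None, genome_id: (position | None, strand), ...}``;
    ``None`` positions mark gapped genomes, and a consensus position inside
    a delimiter run maps to no genome at all.
    """
    if from_genome == 0:
        cons_pos = pos
    else:
        cons_pos, _ = genome_pos_to_consensus(c, from_genome, pos)
    result: dict = {"consensus": cons_pos}
    for gid, gpos, strand in consensus_pos_to_genomes(c, cons_pos):
        result[gid] = (gpos, strand)
    return result


def _kmer_profile(seq: str, k: int = 8) -> np.ndarray:
    from .pairwise import _CLASS
    from .datamodel import seq_codes

    codes = _CLASS[seq_codes(seq.upper())].astype(np.int64)
    n = codes.size
    if n < k:
        return np.zeros(4 ** k)
    valid = codes < 4
    ok = np.ones(n - k + 1, dtype=bool)
    val = np.zeros(n - k + 1, dtype=np.int64)
    for t in range(k):
        val = val * 4 + np.clip(codes[t:n - k + 1 + t], 0, 3)
        ok &= valid[t:n - k + 1 + t]
    counts = np.bincount(val[ok], minlength=4 ** k).astype(float)
    norm = np.linalg.norm(counts)
    return counts / norm if norm else counts


def order_genomes(sequences: list[str], mode: str = "similarity",
                  seed: int | None = None, k: int = 8,
                  similarities: np.ndarray | None = None) -> list[int]:
    """Order genomes (returned as 0-based indices into ``sequences``).

    similarity: cosine similarity of k-mer count profiles stands in for an
    alignment-free similarity score; the genome with the largest summed
    similarity to all others goes first and the rest follow by similarity
    to it.  dissimilarity: the similarity order interleaved front/back (so
    1,2,3,4,5,6 becomes 1,6,2,5,3,4).  given: input order.  random: a
    seeded shuffle.  Precomputed pairwise ``similarities`` may replace the
    built-in score.
    """
    n = len(sequences)
    if mode == "given":
        return list(range(n))
    if mode == "random":
        rng = np.random.default_rng(seed)
        return [int(i) for i in rng.permutation(n)]
    if mode not in ("similarity", "dissimilarity"):
        raise ValueError(f"unknown ordering mode {mode!r}")
    if similarities is None:
        profiles = [_kmer_profile(s, k) for s in sequences]
        similarities = np.array(
            [[float(profiles[i] @ profiles[j]) for j in range(n)] for i in range(n)])
    totals = similarities.sum(axis=1) - np.diag(similarities)
    first = int(np.lexsort((np.arange(n), -totals))[0])
    rest = sorted((i for i in range(n) if i != first),
                  key=lambda i: (-similarities[first, i], i))
    sim_order = [first] + rest
    if mode == "similarity":
        return sim_order
    out = []
    lo, hi = 0, n - 1
    while lo <= hi:
        out.append(sim_order[lo])
        if lo != hi:
            out.append(sim_order[hi])
        lo += 1
        hi -= 1
    return out


def initial_pan(name: str, replicons: Replicons) -> GenomeAlignment:
    """A one-genome pan: one single-sequence block per replicon."""
    record = GenomeRecord(1, name, [(rn, len(seq)) for rn, seq in replicons])
    blocks = []
    offset = 0
    for rn, seq in replicons:
        blocks.append(Block(
            [SequenceEntry(1, offset + 1, offset + len(seq), "+", seq)],
            tag="single_sequence"))
        offset += len(seq)
    return GenomeAlignment([record], blocks)


def build_pan(genomes: list[tuple[str, object]],
              wf: WorkflowConfig | None = None,
              order: str = "similarity",
              seed: int | None = None,
              log=None) -> tuple[GenomeAlignment, ConsensusGenome]:
    """Sequentially build a pan-genome from (name, sequence-or-replicons).

    Genomes are ordered (similarity by default), the first seeds the pan,
    and the rest are folded in with :func:`add_genome`.  Genome ids are
    assigned 1..n in insertion order.
    """
    if not genomes:
        raise SeqPanError("build_pan needs at least one genome")
    wf = wf or WorkflowConfig()
    named = [(name, _as_replicons(g, name)) for name, g in genomes]
    concat = ["".join(seq for _, seq in reps) for _, reps in named]
    perm = order_genomes(concat, mode=order, seed=seed)
    ordered = [named[i] for i in perm]

    pan = initial_pan(ordered[0][0], ordered[0][1])
    c = build_consensus(pan, wf.delimiter_length, wf.tie_policy, wf.seed)
    for name, reps in ordered[1:]:
        pan, c = add_genome(pan, c, reps, name=name, wf=wf)
        if log is not None:
            log(f"added {name}: {len(pan.blocks)} blocks")
    return pan, c
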