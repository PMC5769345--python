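"""Linear consensus genome with delimiter runs and its index bundle.

Each block contributes a majority-vote consensus of exactly one character
per alignment column (gaps never win a vote), so within a block the
consensus coordinate and the alignment column are the same thing.  Blocks
are concatenated with fixed-length runs of ``N`` that keep later alignments
from crossing block borders; the delimiter and gap indexes make the linear
sequence fully reversible into the alignment it summarises.
"""

from __future__ import annotations

import hashlib
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    GAP_CODE,
    GenomeAlignment,
    GenomeRecord,
    ValidationError,
    require_valid,
    seq_codes,
)

DEFAULT_DELIMITER_LENGTH = 1000


@dataclass
class BlockCoords:
    """Index row for one block: its consensus interval and row coordinates."""

    cons_start: int
    cons_end: int
    coords: dict[int, tuple[int, int, str]]  # genome_id -> (start, end, strand)


@dataclass
class ConsensusIndexBundle:
    """The two sidecar structures that make the consensus reversible.

    delimiter_index: sorted (start, length) of every N-delimiter run.
    gap_index: per block, per genome, sorted gap runs as
        (1-based alignment column of the first gap, run length).
    block_table: per block, the consensus interval it occupies and the
        per-genome (start, end, strand).
    genome_table: genome_id -> GenomeRecord (names/replicons, metadata the
        alignment output of a bare aligner would lose).
    """

    delimiter_index: list[tuple[int, int]]
    gap_index: list[dict[int, list[tuple[int, int]]]]
    block_table: list[BlockCoords]
    genome_table: dict[int, GenomeRecord]
    delimiter_length: int = DEFAULT_DELIMITER_LENGTH
    source_ref: str = ""

    _cons_starts: list[int] | None = field(default=None, repr=False, compare=False)
    _genome_intervals: dict[int, list[tuple[int, int, int]]] | None = field(
        default=None, repr=False, compare=False)

    def validate(self) -> None:
        prev_end = 0
        for s, ln in self.delimiter_index:
            if s <= prev_end:
                raise ValidationError("delimiter index unsorted or overlapping")
            if ln != self.delimiter_length:
                raise ValidationError("delimiter runs of unequal length")
            prev_end = s + ln - 1

    # -- lookup helpers ----------------------------------------------------
    def block_at(self, pos: int) -> int | None:
        """Index of the block whose consensus interval contains pos."""
        if self._cons_starts is None:
            self._cons_starts = [r.cons_start for r in self.block_table]
        i = bisect_right(self._cons_starts, pos) - 1
        if i < 0:
            return None
        row = self.block_table[i]
        return i if row.cons_start <= pos <= row.cons_end else None

    def delimiter_at(self, pos: int) -> bool:
        starts = [s for s, _ in self.delimiter_index]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return False
        s, ln = self.delimiter_index[i]
        return s <= pos <= s + ln - 1

    def genome_block_at(self, genome_id: int, pos: int) -> int:
        """Index of the block covering a genome position."""
        if self._genome_intervals is None:
            table: dict[int, list[tuple[int, int, int]]] = {}
            for bi, row in enumerate(self.block_table):
                for gid, (s, e, _strand) in row.coords.items():
                    table.setdefault(gid, []).append((s, e, bi))
            for ivs in table.values():
                ivs.sort()
            self._genome_intervals = table
        ivs = self._genome_intervals.get(genome_id)
        if not ivs:
            raise KeyError(f"unknown genome {genome_id}")
        starts = [s for s, _, _ in ivs]
        i = bisect_right(starts, pos) - 1
        if i < 0 or not (ivs[i][0] <= pos <= ivs[i][1]):
            raise ValidationError(
                f"genome {genome_id} position {pos} uncovered: corrupt index")
        return ivs[i][2]


@dataclass
class ConsensusGenome:
    """The pan-genome's single-sequence stand-in."""

    sequence: str
    delimiter_length: int
    index: ConsensusIndexBundle
    source_alignment: GenomeAlignment | None = None
    source_ref: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def block_consensus(block, tie_policy: str = "lex", rng=None, seed=None) -> str:
    """Majority-vote consensus of one block, one character per column.

    Counting is case-insensitive and gaps never vote, so every column
    yields exactly one uppercase character.  Ties go to the
    lexicographically smallest base under ``tie_policy='lex'`` or to a
    seeded random draw under ``'random'``.
    """
    mat = np.vstack([seq_codes(e.text) for e in block.entries])
    lower = (mat >= 97) & (mat <= 122)
    mat = np.where(lower, mat - 32, mat)
    votes = mat != GAP_CODE
    codes = np.unique(mat[votes])
    counts = np.vstack([(mat == c).sum(axis=0) for c in codes])
    best = counts.argmax(axis=0)  # first (lex-smallest) index on ties
    if tie_policy == "random":
        if rng is None:
            rng = np.random.default_rng(seed)
        maxc = counts.max(axis=0)
        tied_cols = np.flatnonzero((counts == maxc).sum(axis=0) > 1)
        for col in tied_cols:
            choices = np.flatnonzero(counts[:, col] == maxc[col])
            best[col] = rng.choice(choices)
    elif tie_policy != "lex":
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    return codes[best].tobytes().decode("ascii")


def _gap_runs(text: str) -> list[tuple[int, int]]:
    """(1-based column, length) of every gap run in an aligned row."""
    mask = seq_codes(text) == GAP_CODE
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return [(int(s) + 1, int(e - s)) for s, e in zip(starts, ends)]


def build_consensus(a: GenomeAlignment,
                    delimiter_length: int = DEFAULT_DELIMITER_LENGTH,
                    tie_policy: str = "lex",
                    seed=None) -> ConsensusGenome:
    """Concatenate per-block consensuses separated by N-delimiter runs.

    Also builds the delimiter index, the per-block gap index, the block
    table (consensus interval plus per-genome coordinates) and the genome
    table.  With ``tie_policy='lex'`` the result is deterministic; the
    ``'random'`` policy draws tied bases from one seeded stream over
    columns in block order.
    """
    if not a.blocks:
        raise ValidationError("cannot build a consensus from an empty alignment")
    require_valid(a)
    rng = np.random.default_rng(seed) if tie_policy == "random" else None

    parts: list[str] = []
    delimiter_index: list[tuple[int, int]] = []
    gap_index: list[dict[int, list[tuple[int, int]]]] = []
    block_table: list[BlockCoords] = []
    offset = 0
    for bi, block in enumerate(a.blocks):
        if bi:
            delimiter_index.append((offset + 1, delimiter_length))
            parts.append("N" * delimiter_length)
            offset += delimiter_length
        cons = block_consensus(block, tie_policy=tie_policy, rng=rng)
        parts.append(cons)
        gap_index.append({e.genome_id: _gap_runs(e.text) for e in block.entries
                          if e.text.count("-")})
        block_table.append(BlockCoords(
            offset + 1, offset + len(cons),
            {e.genome_id: (e.start, e.end, e.strand) for e in block.entries}))
        offset += len(cons)

    sequence = "".join(parts)
    ref = hashlib.sha1(sequence.encode()).hexdigest()[:12]
    bundle = ConsensusIndexBundle(
        delimiter_index=delimiter_index,
        gap_index=gap_index,
        block_table=block_table,
        genome_table={g.genome_id: g for g in a.genomes},
        delimiter_length=delimiter_length,
        source_ref=ref,
    )
    return ConsensusGenome(sequence, delimiter_length, bundle,
                           source_alignment=a, source_ref=ref)


def _gaps_before(runs: list[tuple[int, int]], column: int) -> int | None:
    """Total gap length at or before ``column``; None if column is a gap."""
    total = 0
    for rs, rl in runs:
        if rs > column:
            break
        if column <= rs + rl - 1:
            return None
        total += rl
    return total


def consensus_pos_to_genomes(c: ConsensusGenome, pos: int):
    """Map a consensus position to every genome.

    Returns a list of ``(genome_id, genome_position_or_None, strand)``;
    ``None`` marks genomes gapped at that column.  A position inside a
    delimiter run returns the empty list.
    """
    if not (1 <= pos <= c.length):
        raise ValueError(f"consensus position {pos} out of range 1..{c.length}")
    idx = c.index
    if idx.delimiter_at(pos):
        return []
    bi = idx.block_at(pos)
    if bi is None:
        raise ValidationError(f"position {pos} in neither block nor delimiter")
    row = idx.block_table[bi]
    column = pos - row.cons_start + 1
    out = []
    for gid, (s, e, strand) in sorted(row.coords.items()):
        runs = idx.gap_index[bi].get(gid, [])
        g = _gaps_before(runs, column)
        if g is None:
            out.append((gid, None, strand))
            continue
        u = column - g  # ordinal of the non-gap character
        out.append((gid, s + u - 1 if strand == "+" else e - u + 1, strand))
    return out


def genome_pos_to_consensus(c: ConsensusGenome, genome_id: int, pos: int) -> tuple[int, str]:
    """Consensus position and strand of one genome position (a bijection
    with :func:`consensus_pos_to_genomes` on non-gap sites)."""
    idx = c.index
    bi = idx.genome_block_at(genome_id, pos)
    row = idx.block_table[bi]
    s, e, strand = row.coords[genome_id]
    u = pos - s + 1 if strand == "+" else e - pos + 1
    acc = 0
    for rs, rl in idx.gap_index[bi].get(genome_id, []):
        if u <= rs - 1 - acc:
            break
        acc += rl
    column = u + acc
    return row.cons_start + column - 1, strand


def consensus_identity_alignment(c: ConsensusGenome) -> GenomeAlignment:
    """The trivial self-alignment of a consensus: one two-row identity block
    per consensus block, delimiter runs as genome-2 single-sequence blocks.

    Useful for overlay/reconstruction round trips: reconstructing this
    alignment must reproduce the source alignment's pairs exactly.
    """
    from .datamodel import Block, SequenceEntry

    blocks = []
    for row in c.index.block_table:
        text = c.sequence[row.cons_start - 1:row.cons_end]
        blocks.append(Block([
            SequenceEntry(1, row.cons_start, row.cons_end, "+", text),
            SequenceEntry(2, row.cons_start, row.cons_end, "+", text),
        ], tag="aligned"))
    for s, ln in c.index.delimiter_index:
        blocks.append(Block([
            SequenceEntry(2, s, s + ln - 1, "+", c.sequence[s - 1:s + ln - 1]),
        ], tag="single_sequence"))
    genomes = [
        GenomeRecord(1, "consensus", [("consensus", c.length)]),
        GenomeRecord(2, "consensus_copy", [("consensus_copy", c.length)]),
    ]
    blocks.sort(key=lambda b: min(e.start for e in b.entries))
    return GenomeAlignment(genomes, blocks)
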