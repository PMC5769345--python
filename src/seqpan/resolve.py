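"""Resolving and reconstruction: splitting blocks at delimiter borders,
aligning leftover single-sequence material, and re-expanding the consensus
row of a pairwise alignment into the full multi-genome alignment.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    GAP_CODE,
    Block,
    GenomeAlignment,
    GenomeRecord,
    SeqPanError,
    SequenceEntry,
    block_slice,
    remove_allgap_columns,
    seq_codes,
)
from .aligner import AlignerConfig, align_pair, sort_pairwise_blocks
from .consensus import ConsensusGenome
from .refine import merge_short_single_blocks, realign_sites


@dataclass
class SuperSequence:
    """Pieces of one genome concatenated with delimiter runs.

    Used both for the leftover-alignment phase and for multi-replicon
    genomes.  ``segments`` maps super coordinates back to the original
    coordinates the pieces came from.
    """

    sequence: str
    segments: list[tuple[int, int, int]]  # (super_start, length, orig_start)
    delimiters: list[tuple[int, int]]  # (super_start, length)

    @classmethod
    def build(cls, pieces: list[tuple[str, int]], delimiter_length: int) -> "SuperSequence":
        parts: list[str] = []
        segments = []
        delimiters = []
        offset = 0
        for i, (seq, orig_start) in enumerate(pieces):
            if i:
                delimiters.append((offset + 1, delimiter_length))
                parts.append("N" * delimiter_length)
                offset += delimiter_length
            segments.append((offset + 1, len(seq), orig_start))
            parts.append(seq)
            offset += len(seq)
        return cls("".join(parts), segments, delimiters)

    def map_interval(self, start: int, end: int) -> tuple[int, int]:
        """Original coordinates of a super interval inside one segment."""
        starts = [s for s, _, _ in self.segments]
        i = bisect_right(starts, start) - 1
        if i < 0:
            raise SeqPanError(f"super position {start} precedes all segments")
        s0, ln, orig = self.segments[i]
        if not (s0 <= start and end <= s0 + ln - 1):
            raise SeqPanError(
                f"super interval {start}-{end} crosses a segment border")
        return orig + (start - s0), orig + (end - s0)


def _drop_genome_rows(block: Block, genome_id: int) -> Block | None:
    """Block without one genome's row; all-gap columns stripped."""
    kept = [e for e in block.entries if e.genome_id != genome_id]
    if not kept:
        return None
    texts = remove_allgap_columns([e.text for e in kept])
    entries = [SequenceEntry(e.genome_id, e.start, e.end, e.strand, t)
               for e, t in zip(kept, texts)]
    tag = "single_sequence" if len(entries) == 1 else block.tag
    return Block(entries, tag=tag)


def split_at_delimiters(a: GenomeAlignment, delimiters: list[tuple[int, int]],
                        target_genome_id: int = 1) -> GenomeAlignment:
    """Split every block whose target-genome row overlaps a delimiter run.

    A block spanning a complete delimiter yields three blocks: two aligned
    flanks and a middle carrying only the *other* genomes' sequence with
    all gaps removed.  A delimiter matched by gaps only is discarded, as
    are target-row delimiter fragments (they are artifacts, not sequence).
    Partial overlaps at a block edge are handled the same way, minus the
    missing flank.
    """
    if not delimiters:
        return a
    starts = [s for s, _ in delimiters]
    new_blocks: list[Block] = []
    for block in a.blocks:
        e = block.entry(target_genome_id)
        if e is None or e.is_empty:
            new_blocks.append(block)
            continue
        i = bisect_right(starts, e.end) - 1
        overlapping = []
        j = bisect_right(starts, e.start) - 1
        j = max(j, 0)
        for s, ln in delimiters[j:i + 1]:
            if s <= e.end and s + ln - 1 >= e.start:
                overlapping.append((max(s, e.start), min(s + ln - 1, e.end)))
        if not overlapping:
            new_blocks.append(block)
            continue
        if e.strand == "-":
            block = block.reverse_complement()
            e = block.entry(target_genome_id)
        cols = np.flatnonzero(seq_codes(e.text) != GAP_CODE)  # 0-based per rank
        cuts = []  # (col_start, col_end, is_delimiter) 1-based
        prev = 1
        for ov_s, ov_e in overlapping:
            c1 = int(cols[ov_s - e.start]) + 1
            c2 = int(cols[ov_e - e.start]) + 1
            if c1 > prev:
                cuts.append((prev, c1 - 1, False))
            cuts.append((c1, c2, True))
            prev = c2 + 1
        if prev <= block.length:
            cuts.append((prev, block.length, False))
        for c1, c2, is_delim in cuts:
            frag = block_slice(block, c1, c2)
            if frag is None:
                continue
            if is_delim:
                frag = _drop_genome_rows(frag, target_genome_id)
                if frag is None:
                    continue  # delimiter matched by gaps only
            elif len(frag.entries) == 1:
                frag.tag = "single_sequence"
            new_blocks.append(frag)
    return GenomeAlignment(a.genomes, new_blocks)


def align_leftovers(a: GenomeAlignment, cfg: AlignerConfig | None = None,
                    delimiter_length: int = 1000,
                    merge: bool = True, merge_max_len: int = 10,
                    realign: bool = True) -> GenomeAlignment:
    """Second-chance alignment of single-sequence blocks.

    Per genome, the forward representation of all single-sequence blocks is
    sorted by genome position and concatenated with delimiter runs; the two
    super-sequences run through the same align/merge/realign pipeline, are
    resolved against each super-sequence's own delimiter index, and the
    surviving blocks are mapped back to original coordinates and replace
    the single-sequence blocks they came from.
    """
    cfg = cfg or AlignerConfig()
    singles = {1: [], 2: []}
    keep: list[Block] = []
    for block in a.blocks:
        if len(block.entries) == 1 and block.entries[0].genome_id in singles:
            singles[block.entries[0].genome_id].append(block)
        else:
            keep.append(block)
    if not singles[1] or not singles[2]:
        return a

    supers = {}
    for gid in (1, 2):
        pieces = []
        for b in sorted(singles[gid], key=lambda b: b.entries[0].start):
            e = b.entries[0]
            pieces.append((e.forward_sequence(), e.start))
        supers[gid] = SuperSequence.build(pieces, delimiter_length)

    pw = align_pair(supers[1].sequence, supers[2].sequence, cfg,
                    name_a="leftover_1", name_b="leftover_2")
    if merge:
        pw = merge_short_single_blocks(pw, merge_max_len)
    if realign:
        pw = realign_sites(pw, cfg.scoring, cfg.band_width)
    pw = split_at_delimiters(pw, supers[1].delimiters, target_genome_id=1)
    pw = split_at_delimiters(pw, supers[2].delimiters, target_genome_id=2)

    remapped: list[Block] = []
    for block in pw.blocks:
        ok = True
        entries = []
        for e in block.entries:
            s, t = supers[e.genome_id].map_interval(e.start, e.end)
            entries.append(SequenceEntry(e.genome_id, s, t, e.strand, e.text))
        if ok:
            remapped.append(Block(entries, tag=block.tag))

    return GenomeAlignment(
        a.genomes, sort_pairwise_blocks(keep + remapped))


def reconstruct(pairwise: GenomeAlignment, c: ConsensusGenome) -> GenomeAlignment:
    """Re-expand the consensus row of a resolved pairwise alignment.

    Every block holding consensus sequence is located in the block table,
    the source block's rows are sliced over the matching columns (consensus
    offset equals alignment column within a block), gap columns the
    pairwise alignment added to the consensus row are inserted into every
    original row, the new genome's row is overlaid, and the consensus row
    itself disappears.  Pairs among previously aligned genomes are exactly
    preserved.
    """
    prev = c.source_alignment
    if prev is None:
        raise SeqPanError("consensus genome carries no source alignment")
    new_gid = len(prev.genomes) + 1
    new_meta = pairwise.genome(2)
    genomes = list(prev.genomes) + [
        GenomeRecord(new_gid, new_meta.name, new_meta.replicons)]

    table = c.index.block_table
    cons_starts = [r.cons_start for r in table]
    cache: dict[int, list[tuple[SequenceEntry, np.ndarray, np.ndarray]]] = {}

    def source_rows(bi: int):
        if bi not in cache:
            rows = []
            for e in prev.blocks[bi].entries:
                codes = seq_codes(e.text)
                cum = np.concatenate(([0], np.cumsum(codes != GAP_CODE)))
                rows.append((e, codes, cum))
            cache[bi] = rows
        return cache[bi]

    out_blocks: list[Block] = []
    for pb in sort_pairwise_blocks(pairwise.blocks):
        e_cons = pb.entry(1)
        e_new = pb.entry(2)
        if e_cons is None or e_cons.is_empty:
            out_blocks.append(Block(
                [SequenceEntry(new_gid, e_new.start, e_new.end, e_new.strand,
                               e_new.text)],
                tag="single_sequence"))
            continue
        if e_cons.strand == "-":
            pb = pb.reverse_complement()
            e_cons = pb.entry(1)
            e_new = pb.entry(2)
        bi = bisect_right(cons_starts, e_cons.start) - 1
        row = table[bi] if bi >= 0 else None
        if row is None or e_cons.end > row.cons_end or e_cons.start < row.cons_start:
            raise SeqPanError(
                f"consensus interval {e_cons.start}-{e_cons.end} not inside a "
                "single consensus block: resolve before reconstructing")
        a0 = e_cons.start - row.cons_start + 1
        b0 = e_cons.end - row.cons_start + 1
        cons_codes = seq_codes(e_cons.text)
        nz = np.flatnonzero(cons_codes != GAP_CODE)
        width = cons_codes.size
        entries = []
        for se, codes, cum in source_rows(bi):
            n_before = int(cum[a0 - 1])
            n_in = int(cum[b0]) - n_before
            if n_in == 0:
                continue
            out = np.full(width, GAP_CODE, dtype=np.uint8)
            out[nz] = codes[a0 - 1:b0]
            if se.strand == "+":
                s = se.start + n_before
                t = s + n_in - 1
            else:
                t = se.end - n_before
                s = t - n_in + 1
            entries.append(SequenceEntry(
                se.genome_id, s, t, se.strand, out.tobytes().decode("ascii")))
        if e_new is not None and not e_new.is_empty:
            entries.append(SequenceEntry(
                new_gid, e_new.start, e_new.end, e_new.strand, e_new.text))
        out_blocks.append(Block(
            entries, tag="aligned" if len(entries) > 1 else "single_sequence"))

    return GenomeAlignment(genomes, out_blocks)
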