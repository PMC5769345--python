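"""Alignment refinement: merging short single-sequence blocks and
realigning consecutive-gap sites.

Merging absorbs short one-sequence blocks into a coordinate-contiguous
neighbouring row, padding the neighbour's other rows with gaps; it never
creates or destroys aligned pairs.  Realignment targets sites where a gap
run in one row is immediately adjacent to a gap run in the other ("
consecutive gaps"), extends the site by the longer gap length, and replaces
the interval with an optimal global realignment whenever that does not
lower the score.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import (
    GAP,
    AlignmentError,
    Block,
    GenomeAlignment,
    SequenceEntry,
    revcomp,
)
from .pairwise import Scoring, global_align, score_alignment


def _copy_alignment(a: GenomeAlignment) -> GenomeAlignment:
    return GenomeAlignment(
        list(a.genomes),
        [Block([SequenceEntry(e.genome_id, e.start, e.end, e.strand, e.text)
                for e in b.entries], tag=b.tag) for b in a.blocks])


@dataclass
class ConsecutiveGapSite:
    """A column interval where one row's gap run abuts the other row's."""

    block: Block
    start_col: int  # 1-based inclusive
    end_col: int


def _gap_run_list(text: str) -> list[tuple[int, int]]:
    """(start_col, end_col) 1-based of every gap run."""
    runs = []
    start = None
    for i, ch in enumerate(text, start=1):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(text)))
    return runs


def find_consecutive_gap_sites(block: Block) -> list[ConsecutiveGapSite]:
    """Maximal intervals where a gap run of one row is immediately followed
    by a gap run of the other row (in either order).  Defined for two-row
    blocks; others yield no sites."""
    if len(block.entries) != 2:
        return []
    runs = [_gap_run_list(e.text) for e in block.entries]
    raw: list[tuple[int, int]] = []
    for first, second in ((0, 1), (1, 0)):
        starts = {s: e for s, e in runs[second]}
        for s, e in runs[first]:
            if e + 1 in starts:
                raw.append((s, starts[e + 1]))
    if not raw:
        return []
    raw.sort()
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [ConsecutiveGapSite(block, s, e) for s, e in merged]


def merge_short_single_blocks(a: GenomeAlignment, max_len: int = 10) -> GenomeAlignment:
    """Absorb single-sequence blocks of length <= max_len into a
    coordinate-contiguous neighbouring block of the same genome.

    The 5' neighbour (the block whose row ends at start-1 on the forward
    strand) is preferred; the 3' neighbour is the fallback.  Other rows of
    the receiving block are padded with a gap run at the junction.  Short
    blocks with no contiguous neighbour stay in place.  Aligned pairs are
    unchanged: appended columns carry a single non-gap character.
    """
    out = _copy_alignment(a)
    blocks = out.blocks

    def try_merge(sb: Block) -> bool:
        se = sb.entries[0]
        gid, s, e = se.genome_id, se.start, se.end
        seq = se.text  # single blocks are gap-free, forward
        for other in blocks:
            if other is sb:
                continue
            oe = other.entry(gid)
            if oe is None or oe.is_empty:
                continue
            if oe.end == s - 1:  # 5' neighbour
                if oe.strand == "+":  # extend at the block's right edge
                    pad = GAP * len(seq)
                    for en in other.entries:
                        en.text = en.text + (seq if en is oe else pad)
                    oe.end = e
                else:  # "-" row: forward end sits at the block's left edge
                    pad = GAP * len(seq)
                    rc = revcomp(seq)
                    for en in other.entries:
                        en.text = (rc if en is oe else pad) + en.text
                    oe.end = e
                return True
        for other in blocks:
            if other is sb:
                continue
            oe = other.entry(gid)
            if oe is None or oe.is_empty:
                continue
            if oe.start == e + 1:  # 3' neighbour
                pad = GAP * len(seq)
                if oe.strand == "+":
                    for en in other.entries:
                        en.text = (seq if en is oe else pad) + en.text
                    oe.start = s
                else:
                    rc = revcomp(seq)
                    for en in other.entries:
                        en.text = en.text + (rc if en is oe else pad)
                    oe.start = s
                return True
        return False

    changed = True
    while changed:
        changed = False
        shorts = sorted(
            (b for b in blocks
             if len(b.entries) == 1 and not b.entries[0].is_empty
             and b.length <= max_len),
            key=lambda b: (b.entries[0].genome_id, b.entries[0].start))
        for sb in shorts:
            if try_merge(sb):
                blocks.remove(sb)
                changed = True
    return out


def realign_sites(a: GenomeAlignment, scoring: Scoring | None = None,
                  band_width: int = 64) -> GenomeAlignment:
    """Realign every consecutive-gap site of every two-row block.

    Each site is extended on both sides by the longer gap length (clipped
    at block borders), the two ungapped sub-sequences are realigned
    optimally, and the columns are spliced back when the score does not
    decrease.  Genome sequences and coordinates are untouched.
    """
    scoring = scoring or Scoring()
    out = _copy_alignment(a)
    for block in out.blocks:
        if len(block.entries) != 2:
            continue
        sites = find_consecutive_gap_sites(block)
        if not sites:
            continue
        e1, e2 = block.entries
        intervals: list[list[int]] = []
        for site in sites:
            seg1 = e1.text[site.start_col - 1:site.end_col]
            seg2 = e2.text[site.start_col - 1:site.end_col]
            ext = max(seg1.count(GAP), seg2.count(GAP))
            lo = max(1, site.start_col - ext)
            hi = min(block.length, site.end_col + ext)
            if intervals and lo <= intervals[-1][1] + 1:
                intervals[-1][1] = max(intervals[-1][1], hi)
            else:
                intervals.append([lo, hi])
        for lo, hi in reversed(intervals):
            t1 = e1.text[lo - 1:hi]
            t2 = e2.text[lo - 1:hi]
            s1 = t1.replace(GAP, "")
            s2 = t2.replace(GAP, "")
            if not s1 or not s2:
                continue
            old = score_alignment(t1, t2, scoring)
            try:
                score, a1, a2 = global_align(s1, s2, scoring, band_width)
            except AlignmentError:
                continue  # interval too large to realign optimally; keep as is
            if score >= old and (a1, a2) != (t1, t2):
                e1.text = e1.text[:lo - 1] + a1 + e1.text[hi:]
                e2.text = e2.text[:lo - 1] + a2 + e2.text[hi:]
    return out
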