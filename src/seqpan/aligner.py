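"""Anchor-based pairwise genome alignment.

The alignment step partitions two genomes into locally collinear blocks:
maximal runs of unique k-mer matches are chained by collinearity and
strand, inter-anchor gaps are closed with banded global alignment, and
territory no chain claims is emitted as single-sequence blocks.  The module
also ingests an external aligner's pairwise XMFA so any backend producing
the same dialect can stand in for the built-in aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    AlignmentError,
    Block,
    GenomeAlignment,
    GenomeRecord,
    SequenceEntry,
    ValidationError,
    require_valid,
    revcomp,
)
from .pairwise import Scoring, global_align


@dataclass(frozen=True)
class AlignerConfig:
    """Tunables of the built-in aligner.

    k is the anchor seed length; chains supported by fewer than
    ``min_chain_anchors`` seed matches are discarded as spurious.
    ``band_width`` seeds the gap-filling band, which doubles on demand up to
    ``max_cells`` DP cells.
    """

    k: int = 15
    min_chain_anchors: int = 2
    band_width: int = 64
    scoring: Scoring = field(default_factory=Scoring)
    min_lcb_length: int = 0
    chain_gap_weight: float = 0.5
    max_fill_gap: int = 200
    max_cells: int = 60_000_000

    def __post_init__(self):
        if self.k < 8:
            raise ValueError("anchor k-mer length must be >= 8")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")


@dataclass
class Anchor:
    """A maximal exact match seeded by k-mers unique in both sequences."""

    a: int  # 1-based start in A
    b: int  # 1-based start in B (forward strand)
    length: int
    strand: str  # strand of B relative to A

    @property
    def a_end(self) -> int:
        return self.a + self.length - 1

    @property
    def b_end(self) -> int:
        return self.b + self.length - 1


@dataclass
class Chain:
    """A collinear, consistently-stranded, non-crossing run of anchors."""

    anchors: list[Anchor]
    strand: str

    @property
    def a_start(self) -> int:
        return self.anchors[0].a

    @property
    def a_end(self) -> int:
        return self.anchors[-1].a_end

    @property
    def b_start(self) -> int:
        return min(x.b for x in self.anchors)

    @property
    def b_end(self) -> int:
        return max(x.b_end for x in self.anchors)

    def support(self, k: int) -> int:
        return sum(max(x.length - k + 1, 1) for x in self.anchors)


_ACGT = frozenset("ACGT")


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    """k-mer -> 1-based position for k-mers occurring exactly once.

    Duplicated k-mers map to -1; k-mers containing anything outside ACGT
    (notably delimiter N runs) are never recorded.
    """
    table: dict[str, int] = {}
    taint = -1  # 0-based index of the last non-ACGT char seen
    for i, ch in enumerate(seq):
        if ch not in _ACGT:
            taint = i
        start = i - k + 1
        if start < 0 or taint >= start:
            continue
        kmer = seq[start:i + 1]
        if kmer in table:
            table[kmer] = -1
        else:
            table[kmer] = start + 1
    return table


def find_unique_anchors(seq_a: str, seq_b: str, k: int) -> list[Anchor]:
    """All maximal exact-match runs seeded by k-mers unique in both inputs.

    Both orientations are reported; a k-mer is usable on B only when its
    forward and reverse-complement occurrences there total exactly one.
    """
    ua = seq_a.upper()
    ub = seq_b.upper()
    if k > min(len(ua), len(ub)):
        return []
    tab_a = _unique_kmers(ua, k)
    tab_b = _unique_kmers(ub, k)

    fwd: list[tuple[int, int]] = []  # (a, b) seed starts
    rev: list[tuple[int, int]] = []
    for kmer, pa in tab_a.items():
        if pa < 0:
            continue
        rc = revcomp(kmer)
        if rc == kmer:
            continue  # palindromic seeds are orientation-ambiguous
        pb = tab_b.get(kmer)
        pr = tab_b.get(rc)
        if pb is not None and pb > 0 and pr is None:
            fwd.append((pa, pb))
        elif pb is None and pr is not None and pr > 0:
            rev.append((pa, pr))

    anchors: list[Anchor] = []
    # merge forward seeds along diagonals
    fwd.sort(key=lambda s: (s[1] - s[0], s[0]))
    cur: list[int] | None = None
    for pa, pb in fwd:
        if cur is not None and pb - pa == cur[2] and pa <= cur[0] + cur[1]:
            cur[1] = pa + k - cur[0]
        else:
            if cur is not None:
                anchors.append(Anchor(cur[0], cur[0] + cur[2], cur[1], "+"))
            cur = [pa, k, pb - pa]
    if cur is not None:
        anchors.append(Anchor(cur[0], cur[0] + cur[2], cur[1], "+"))

    # merge reverse seeds along anti-diagonals: seed (a, b) pairs A[a..] with
    # rc of B[b..]; the neighbour seed is (a+1, b-1).
    rev.sort(key=lambda s: (s[0] + s[1], s[0]))
    cur = None
    for pa, pb in rev:
        if cur is not None and pa + pb == cur[2] and pa <= cur[0] + cur[1]:
            cur[1] = pa + k - cur[0]
        else:
            if cur is not None:
                anchors.append(Anchor(cur[0], cur[2] - (cur[0] + cur[1] - k), cur[1], "-"))
            cur = [pa, k, pa + pb]
    if cur is not None:
        anchors.append(Anchor(cur[0], cur[2] - (cur[0] + cur[1] - k), cur[1], "-"))

    _extend_anchors(anchors, ua, ub)
    anchors.sort(key=lambda x: (x.a, x.b))
    return anchors


_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _extend_anchors(anchors: list[Anchor], ua: str, ub: str) -> None:
    """Grow merged runs outward while characters keep matching exactly.

    Only A/C/G/T may extend a run, so delimiter N stretches still cannot be
    anchored."""
    na, nb = len(ua), len(ub)
    for x in anchors:
        if x.strand == "+":
            while (x.a > 1 and x.b > 1 and ua[x.a - 2] == ub[x.b - 2]
                   and ua[x.a - 2] in _ACGT):
                x.a -= 1
                x.b -= 1
                x.length += 1
            while (x.a_end < na and x.b_end < nb
                   and ua[x.a_end] == ub[x.b_end] and ua[x.a_end] in _ACGT):
                x.length += 1
        else:
            # A-front pairs with B-end, A-back with B-front
            while (x.a > 1 and x.b_end < nb
                   and (ua[x.a - 2], ub[x.b_end]) in _PAIR):
                x.a -= 1
                x.length += 1
            while (x.a_end < na and x.b > 1
                   and (ua[x.a_end], ub[x.b - 2]) in _PAIR):
                x.b -= 1
                x.length += 1


def _compatible(prev: Anchor, nxt: Anchor, max_overlap: int) -> bool:
    if prev.strand != nxt.strand:
        return False
    if not (nxt.a > prev.a and nxt.a_end > prev.a_end):
        return False
    if prev.a_end - nxt.a + 1 > max_overlap:
        return False
    if prev.strand == "+":
        if not (nxt.b > prev.b and nxt.b_end > prev.b_end):
            return False
        return prev.b_end - nxt.b + 1 <= max_overlap
    # reverse strand: B intervals must decrease with A
    if not (nxt.b < prev.b and nxt.b_end < prev.b_end):
        return False
    return nxt.b_end - prev.b + 1 <= max_overlap


def _trim_chain(anchors: list[Anchor]) -> list[Anchor]:
    """Remove residual overlaps between consecutive anchors by trimming."""
    out: list[Anchor] = []
    for x in anchors:
        x = Anchor(x.a, x.b, x.length, x.strand)
        if out:
            prev = out[-1]
            t = prev.a_end - x.a + 1
            if t > 0:
                x.a += t
                x.length -= t
                if x.strand == "+":
                    x.b += t
            if x.length <= 0:
                continue
            if x.strand == "+":
                t = prev.b_end - x.b + 1
                if t > 0:
                    x.a += t
                    x.b += t
                    x.length -= t
            else:
                t = x.b_end - prev.b + 1
                if t > 0:  # trimming the A-front of a "-" anchor lowers b_end
                    x.a += t
                    x.length -= t
            if x.length <= 0:
                continue
        out.append(x)
    return out


def _bridge(prev: Anchor, nxt: Anchor) -> tuple[tuple[int, int], tuple[int, int]]:
    """The (A interval, B interval) a prev->nxt transition spans."""
    ba = (prev.a_end + 1, nxt.a - 1)
    if prev.strand == "+":
        bb = (prev.b_end + 1, nxt.b - 1)
    else:
        bb = (nxt.b_end + 1, prev.b - 1)
    return ba, bb


def chain_anchors(anchors: list[Anchor], max_overlap: int = 14,
                  gap_weight: float = 0.5, max_fill_gap: int = 200) -> list[Chain]:
    """Partition anchors into maximal collinear chains.

    Repeatedly extracts the chain maximising total anchored length minus
    ``gap_weight`` times the inter-anchor gap (ties broken toward the
    smaller A start) by a longest-increasing-subsequence style DP.  An
    extracted chain is cut at links whose gap exceeds ``max_fill_gap`` on
    either sequence, so material inside large skipped gaps (small
    inversions, translocated segments) stays available to later chains;
    anchors overlapping an extracted span are trimmed away, and later
    chains may not bridge across an extracted span.  Chain spans therefore
    never overlap; crossing or strand-flipped anchors end up in separate
    chains.
    """
    remaining = sorted(anchors, key=lambda x: (x.a, x.b))
    chains: list[Chain] = []
    spans_a: list[tuple[int, int]] = []
    spans_b: list[tuple[int, int]] = []

    def blocked(prev: Anchor, nxt: Anchor) -> bool:
        (a0, a1), (b0, b1) = _bridge(prev, nxt)
        for s, e in spans_a:
            if s <= a1 and e >= a0:
                return True
        for s, e in spans_b:
            if s <= b1 and e >= b0:
                return True
        return False

    while remaining:
        n = len(remaining)
        dp = [float(x.length) for x in remaining]
        back = [-1] * n
        for i in range(n):
            xi = remaining[i]
            for j in range(i):
                xj = remaining[j]
                if _compatible(xj, xi, max_overlap) and not blocked(xj, xi):
                    da = max(0, xi.a - xj.a_end - 1)
                    if xi.strand == "+":
                        db = max(0, xi.b - xj.b_end - 1)
                    else:
                        db = max(0, xj.b - xi.b_end - 1)
                    cand = dp[j] + xi.length - gap_weight * max(da, db)
                    if cand > dp[i]:
                        dp[i] = cand
                        back[i] = j
        best = max(range(n), key=lambda i: (dp[i], -remaining[i].a))
        picked = []
        i = best
        while i >= 0:
            picked.append(remaining[i])
            i = back[i]
        picked.reverse()
        picked = _trim_chain(picked)
        if not picked:
            remaining.pop(best)
            continue
        new_spans_a = []
        new_spans_b = []
        for part in _split_at_large_gaps(picked, max_fill_gap):
            chain = Chain(part, part[0].strand)
            chains.append(chain)
            new_spans_a.append((chain.a_start, chain.a_end))
            new_spans_b.append((chain.b_start, chain.b_end))
        spans_a.extend(new_spans_a)
        spans_b.extend(new_spans_b)
        min_len = max_overlap + 1
        survivors: list[Anchor] = []
        for x in remaining:
            survivors.extend(
                _clip_outside(x, new_spans_a, new_spans_b, min_len))
        remaining = sorted(survivors, key=lambda x: (x.a, x.b))
    chains.sort(key=lambda c: c.a_start)
    return chains


def _split_at_large_gaps(anchors: list[Anchor], max_fill_gap: int) -> list[list[Anchor]]:
    parts: list[list[Anchor]] = [[anchors[0]]]
    for prev, nxt in zip(anchors, anchors[1:]):
        da = nxt.a - prev.a_end - 1
        if prev.strand == "+":
            db = nxt.b - prev.b_end - 1
        else:
            db = prev.b - nxt.b_end - 1
        if max(da, db) > max_fill_gap:
            parts.append([])
        parts[-1].append(nxt)
    return parts


def _clip_outside(x: Anchor, spans_a, spans_b, min_len: int) -> list[Anchor]:
    """Parts of an anchor lying outside claimed spans on both sequences.

    Anchors are exact matches, so cutting them at span borders keeps them
    exact; parts shorter than ``min_len`` are discarded as noise.
    """
    work = [x]
    out: list[Anchor] = []
    while work:
        x = work.pop()
        cut = None
        for s, e in spans_a:
            if s <= x.a_end and e >= x.a:
                cut = (max(s, x.a), min(e, x.a_end))
                break
        if cut is None:
            for s, e in spans_b:
                if s <= x.b_end and e >= x.b:
                    ov_lo = max(s, x.b)
                    ov_hi = min(e, x.b_end)
                    if x.strand == "+":
                        cut = (x.a + (ov_lo - x.b), x.a + (ov_hi - x.b))
                    else:
                        cut = (x.a_end - (ov_hi - x.b), x.a_end - (ov_lo - x.b))
                    break
        if cut is None:
            out.append(x)
            continue
        s, e = cut
        left_len = s - x.a
        right_len = x.a_end - e
        if left_len >= min_len:
            if x.strand == "+":
                work.append(Anchor(x.a, x.b, left_len, "+"))
            else:
                work.append(Anchor(x.a, x.b_end - left_len + 1, left_len, "-"))
        if right_len >= min_len:
            if x.strand == "+":
                work.append(Anchor(e + 1, x.b + (e + 1 - x.a), right_len, "+"))
            else:
                work.append(Anchor(e + 1, x.b, right_len, "-"))
    return out


def _uncovered(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for s, e in sorted(intervals):
        if s > prev + 1:
            out.append((prev + 1, s - 1))
        prev = max(prev, e)
    if prev < length:
        out.append((prev + 1, length))
    return out


def _fill(fa: str, fb: str, cfg: AlignerConfig,
          fallback: bool = False) -> tuple[str, str]:
    if not fa and not fb:
        return "", ""
    if not fa:
        return "-" * len(fb), fb
    if not fb:
        return fa, "-" * len(fa)
    try:
        _, aa, ab = global_align(fa, fb, cfg.scoring, cfg.band_width, cfg.max_cells)
    except AlignmentError:
        if not fallback:
            raise
        # unanchored flank too large to align optimally: leave it unaligned
        return fa + "-" * len(fb), "-" * len(fa) + fb
    return aa, ab


def _compose_chain_block(seq_a: str, seq_b: str, chain: Chain,
                         span_a: tuple[int, int], span_b: tuple[int, int],
                         cfg: AlignerConfig) -> Block:
    """Two-row block for a chain, gap-filling between (and around) anchors."""
    a0, a1 = span_a
    b0, b1 = span_b
    if chain.strand == "+":
        bwork = seq_b[b0 - 1:b1]

        def bcol(pos: int) -> int:  # B forward pos -> 1-based pos in bwork
            return pos - b0 + 1
    else:
        bwork = revcomp(seq_b[b0 - 1:b1])

        def bcol(pos: int) -> int:
            return b1 - pos + 1

    parts_a: list[str] = []
    parts_b: list[str] = []
    cur_a = a0
    cur_b = 1  # in bwork coordinates
    first = True
    for x in chain.anchors:
        if chain.strand == "+":
            xb = bcol(x.b)
        else:
            xb = bcol(x.b_end)  # A-front of a "-" anchor pairs with B end
        fa = seq_a[cur_a - 1:x.a - 1]
        fb = bwork[cur_b - 1:xb - 1]
        aa, ab = _fill(fa, fb, cfg, fallback=first)
        first = False
        parts_a.append(aa)
        parts_b.append(ab)
        parts_a.append(seq_a[x.a - 1:x.a_end])
        parts_b.append(bwork[xb - 1:xb + x.length - 1])
        cur_a = x.a_end + 1
        cur_b = xb + x.length
    aa, ab = _fill(seq_a[cur_a - 1:a1], bwork[cur_b - 1:], cfg, fallback=True)
    parts_a.append(aa)
    parts_b.append(ab)

    text_a = "".join(parts_a)
    text_b = "".join(parts_b)
    entries = [
        SequenceEntry(1, a0, a1, "+", text_a),
        SequenceEntry(2, b0, b1, chain.strand, text_b),
    ]
    return Block(entries, tag="aligned")


def align_pair(seq_a: str, seq_b: str, cfg: AlignerConfig | None = None,
               name_a: str = "A", name_b: str = "B",
               validate: bool = True) -> GenomeAlignment:
    """Pairwise alignment of two sequences as locally collinear blocks.

    Genome 1 is ``seq_a`` (which may be a delimiter-carrying consensus),
    genome 2 is ``seq_b``.  Both sequences are fully covered: chained
    regions become two-row blocks, everything else single-sequence blocks.
    """
    cfg = cfg or AlignerConfig()
    anchors = find_unique_anchors(seq_a, seq_b, cfg.k)
    chains = [c for c in chain_anchors(anchors, max_overlap=cfg.k - 1,
                                       gap_weight=cfg.chain_gap_weight,
                                       max_fill_gap=cfg.max_fill_gap)
              if c.support(cfg.k) >= cfg.min_chain_anchors]
    if cfg.min_lcb_length > 0:
        chains = [c for c in chains
                  if c.a_end - c.a_start + 1 >= cfg.min_lcb_length]

    # flank absorption: a chain that is extreme in A order and on its
    # matching side in B order soaks up the unanchored terminal flanks,
    # provided both flanks are non-empty.
    spans: dict[int, list[int]] = {
        id(c): [c.a_start, c.a_end, c.b_start, c.b_end] for c in chains}
    if chains:
        by_b = sorted(chains, key=lambda c: c.b_start)
        first_a, last_a = chains[0], chains[-1]
        for chain, left in ((first_a, True), (last_a, False)):
            sp = spans[id(chain)]
            if left:
                free_a = sp[0] > 1
            else:
                free_a = sp[1] < len(seq_a)
            b_left = (chain.strand == "+") == left
            if b_left:
                free_b = chain is by_b[0] and sp[2] > 1
            else:
                free_b = chain is by_b[-1] and sp[3] < len(seq_b)
            if free_a and free_b:
                if left:
                    sp[0] = 1
                else:
                    sp[1] = len(seq_a)
                if b_left:
                    sp[2] = 1
                else:
                    sp[3] = len(seq_b)

    blocks: list[Block] = []
    cov_a: list[tuple[int, int]] = []
    cov_b: list[tuple[int, int]] = []
    for chain in chains:
        sp = spans[id(chain)]
        blocks.append(_compose_chain_block(
            seq_a, seq_b, chain, (sp[0], sp[1]), (sp[2], sp[3]), cfg))
        cov_a.append((sp[0], sp[1]))
        cov_b.append((sp[2], sp[3]))

    for s, e in _uncovered(cov_a, len(seq_a)):
        blocks.append(Block(
            [SequenceEntry(1, s, e, "+", seq_a[s - 1:e])], tag="single_sequence"))
    for s, e in _uncovered(cov_b, len(seq_b)):
        blocks.append(Block(
            [SequenceEntry(2, s, e, "+", seq_b[s - 1:e])], tag="single_sequence"))

    genomes = [
        GenomeRecord(1, name_a, [(name_a, len(seq_a))]),
        GenomeRecord(2, name_b, [(name_b, len(seq_b))]),
    ]
    result = GenomeAlignment(genomes, sort_pairwise_blocks(blocks))
    if validate:
        require_valid(result)
    return result


def sort_pairwise_blocks(blocks: list[Block], ref_gid: int = 1,
                         other_gid: int = 2) -> list[Block]:
    """Order blocks by reference position; other-genome-only blocks slot in
    after the block holding their preceding other-genome base."""
    ref_blocks = sorted(
        (b for b in blocks if b.entry(ref_gid) is not None),
        key=lambda b: b.entry(ref_gid).start)
    keys: list[tuple[float, float]] = []
    intervals = []  # (start, end, key) over other genome
    for rank, b in enumerate(ref_blocks):
        keys.append((float(rank), 0.0))
        e = b.entry(other_gid)
        if e is not None and not e.is_empty:
            intervals.append((e.start, e.end, float(rank)))
    intervals.sort()
    ordered = list(zip(keys, ref_blocks))
    for b in blocks:
        if b.entry(ref_gid) is not None:
            continue
        e = b.entry(other_gid)
        key = -1.0
        if e is not None and e.start > 1:
            for s, t, k in intervals:
                if s <= e.start - 1 <= t:
                    key = k
                    break
        ordered.append(((key, 0.5 + (e.start if e else 0) * 1e-12), b))
    ordered.sort(key=lambda kb: kb[0])
    return [b for _, b in ordered]


def ingest_external_pairwise(xmfa_path, id_a: int = 1, id_b: int = 2) -> GenomeAlignment:
    """Load a two-genome XMFA produced by an external aligner.

    Sequence numbers ``id_a``/``id_b`` are renumbered to 1/2 and the result
    is validated, so downstream steps are agnostic to the backend.
    """
    from .io_formats import load_xmfa

    a = load_xmfa(xmfa_path)
    known = {id_a: 1, id_b: 2}
    for block in a.blocks:
        for e in block.entries:
            if e.genome_id not in known:
                raise ValidationError(
                    f"external alignment contains unexpected sequence {e.genome_id}")
            e.genome_id = known[e.genome_id]
    genomes = []
    for old, new in known.items():
        g = a.genome(old)
        genomes.append(GenomeRecord(new, g.name, g.replicons))
    out = GenomeAlignment(sorted(genomes, key=lambda g: g.genome_id),
                          sort_pairwise_blocks(a.blocks))
    require_valid(out)
    return out
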