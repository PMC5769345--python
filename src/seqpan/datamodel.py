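"""Core data model: genomes, alignment blocks and aligned-pair sets.

A whole genome alignment is an ordered list of locally collinear blocks
(LCBs).  Each block is a gap-padded multiple alignment with at most one row
per genome.  Rows carry 1-based inclusive forward-strand coordinates; a
reverse-strand row stores the reverse complement of the forward genome
slice, exactly as the text appears in the alignment (XMFA convention).

Coordinates are 1-based inclusive throughout the public surface.  The
canonical empty row uses ``start == end == 0`` (the Mauve-family "0-0"
dialect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

GAP = "-"
GAP_CODE = ord(GAP)

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv-",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb-",
)


class SeqPanError(Exception):
    """Base error for this package."""


class ValidationError(SeqPanError):
    """Raised when an operation requires a valid alignment and gets none."""


class FormatError(SeqPanError):
    """Raised on malformed input files."""


class AlignmentError(SeqPanError):
    """Raised when the internal aligner cannot produce an alignment."""


def revcomp(seq: str) -> str:
    """Reverse complement, case preserving; IUPAC codes are complemented."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_codes(text: str) -> np.ndarray:
    """View of ``text`` as a uint8 array of ASCII codes (read-only)."""
    return np.frombuffer(text.encode("ascii"), dtype=np.uint8)


def _nongap_count(text: str) -> int:
    return len(text) - text.count(GAP)


@dataclass
class GenomeRecord:
    """One input genome: stable id, FASTA header, replicon layout.

    ``replicons`` is an ordered list of ``(replicon_name, length)``.
    Genome-global coordinates run 1..total_length over the concatenated
    replicons (no padding between replicons in the coordinate system).
    """

    genome_id: int
    name: str
    replicons: list[tuple[str, int]]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.replicons)

    def replicon_interval(self, replicon_name: str) -> tuple[int, int]:
        """Genome-global (start, end) of one replicon."""
        offset = 0
        for name, length in self.replicons:
            if name == replicon_name:
                return offset + 1, offset + length
            offset += length
        raise KeyError(replicon_name)

    def locate(self, pos: int) -> tuple[str, int]:
        """Replicon name and replicon-local position for a global position."""
        offset = 0
        for name, length in self.replicons:
            if pos <= offset + length:
                return name, pos - offset
            offset += length
        raise ValueError(f"position {pos} beyond genome {self.genome_id}")


@dataclass
class SequenceEntry:
    """One aligned row of a block.

    ``start``/``end`` are 1-based inclusive forward-strand genome
    coordinates of the leftmost/rightmost aligned base.  For ``strand ==
    '-'`` the stored ``text`` is the reverse complement of the forward
    genome slice.
    """

    genome_id: int
    start: int
    end: int
    strand: str
    text: str

    @property
    def is_empty(self) -> bool:
        return self.start == 0 and self.end == 0

    @property
    def nongap_length(self) -> int:
        return _nongap_count(self.text)

    def ungapped(self) -> str:
        return self.text.replace(GAP, "")

    def forward_sequence(self) -> str:
        """The genome slice on the forward strand, gaps removed."""
        seq = self.ungapped()
        return revcomp(seq) if self.strand == "-" else seq

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column (non-gap mask, forward-strand genome position).

        Positions are meaningful only where the mask is True.
        """
        mask = seq_codes(self.text) != GAP_CODE
        cum = np.cumsum(mask)
        if self.strand == "+":
            pos = self.start - 1 + cum
        else:
            pos = self.end + 1 - cum
        return mask, pos


@dataclass
class Block:
    """A locally collinear block: one row per participating genome."""

    entries: list[SequenceEntry]
    tag: str = "aligned"  # {aligned, single_sequence, delimiter_artifact}

    @property
    def length(self) -> int:
        return len(self.entries[0].text) if self.entries else 0

    def genome_ids(self) -> list[int]:
        return [e.genome_id for e in self.entries]

    def entry(self, genome_id: int) -> SequenceEntry | None:
        for e in self.entries:
            if e.genome_id == genome_id:
                return e
        return None

    def reverse_complement(self) -> "Block":
        """The same block read right-to-left (all strands flipped)."""
        flipped = [
            SequenceEntry(
                e.genome_id, e.start, e.end,
                "-" if e.strand == "+" else "+", revcomp(e.text),
            )
            for e in self.entries
        ]
        return Block(flipped, tag=self.tag)


def remove_allgap_columns(texts: list[str]) -> list[str]:
    """Delete columns that are gaps in every row."""
    if not texts:
        return texts
    mat = np.vstack([seq_codes(t) for t in texts])
    keep = (mat != GAP_CODE).any(axis=0)
    if keep.all():
        return texts
    mat = mat[:, keep]
    return [m.tobytes().decode("ascii") for m in mat]


def block_slice(block: Block, col_start: int, col_end: int,
                tag: str | None = None) -> Block | None:
    """Sub-block over 1-based inclusive columns [col_start, col_end].

    Rows that are all-gap in the range are dropped; columns that become
    all-gap across the remaining rows are removed.  Returns None when no
    row has sequence in the range.
    """
    sub_entries = []
    for e in block.entries:
        sub = e.text[col_start - 1:col_end]
        n_in = _nongap_count(sub)
        if n_in == 0:
            continue
        n_before = _nongap_count(e.text[:col_start - 1])
        if e.strand == "+":
            s = e.start + n_before
            t = s + n_in - 1
        else:
            t = e.end - n_before
            s = t - n_in + 1
        sub_entries.append(SequenceEntry(e.genome_id, s, t, e.strand, sub))
    if not sub_entries:
        return None
    texts = remove_allgap_columns([e.text for e in sub_entries])
    for e, txt in zip(sub_entries, texts):
        e.text = txt
    return Block(sub_entries, tag=tag if tag is not None else block.tag)


@dataclass
class GenomeAlignment:
    """An ordered set of blocks plus genome metadata: the pan-genome."""

    genomes: list[GenomeRecord]
    blocks: list[Block] = field(default_factory=list)

    def genome(self, genome_id: int) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(f"unknown genome {genome_id}")

    def genome_ids(self) -> list[int]:
        return [g.genome_id for g in self.genomes]


class PairSet:
    """The set of aligned residue pairs implied by an alignment.

    Pairs are canonical tuples ``((g_i, pos_i), (g_j, pos_j), orientation)``
    with ``g_i < g_j``, positions 1-based forward-strand, orientation in
    {"same", "opposite"}.  Internally pairs are bit-packed into a sorted
    int64 array so that intersections over millions of pairs stay cheap;
    this caps genome ids below 64 and positions below 2**25.
    """

    _PBITS = 25
    _GBITS = 6
    _PMAX = (1 << _PBITS) - 1
    _GMAX = (1 << _GBITS) - 1

    def __init__(self, packed: np.ndarray | None = None):
        if packed is None:
            packed = np.empty(0, dtype=np.int64)
        self._packed = np.unique(np.asarray(packed, dtype=np.int64))

    # -- construction -----------------------------------------------------
    @classmethod
    def pack_arrays(cls, gi, pi, gj, pj, opposite) -> np.ndarray:
        """Pack parallel arrays of pair fields into int64 codes."""
        gi = np.asarray(gi, dtype=np.int64)
        gj = np.asarray(gj, dtype=np.int64)
        pi = np.asarray(pi, dtype=np.int64)
        pj = np.asarray(pj, dtype=np.int64)
        opp = np.asarray(opposite, dtype=np.int64)
        swap = gi > gj
        if np.any(swap):
            gi, gj = np.where(swap, gj, gi), np.where(swap, gi, gj)
            pi, pj = np.where(swap, pj, pi), np.where(swap, pi, pj)
        if gi.size and (int(gj.max()) > cls._GMAX or int(max(pi.max(), pj.max())) > cls._PMAX):
            raise ValueError("pair fields exceed PairSet packing capacity")
        return (((((gi << cls._GBITS) | gj) << cls._PBITS) | pi) << (cls._PBITS + 1)) | (pj << 1) | opp

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "PairSet":
        gi, pi, gj, pj, opp = [], [], [], [], []
        for (a, pa), (b, pb), orientation in pairs:
            gi.append(a)
            pi.append(pa)
            gj.append(b)
            pj.append(pb)
            opp.append(0 if orientation == "same" else 1)
        if not gi:
            return cls()
        return cls(cls.pack_arrays(gi, pi, gj, pj, opp))

    # -- set behaviour ----------------------------------------------------
    def __len__(self) -> int:
        return int(self._packed.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PairSet):
            return NotImplemented
        return np.array_equal(self._packed, other._packed)

    def __hash__(self):  # pragma: no cover - sets of PairSets are unused
        return hash(self._packed.tobytes())

    def intersection(self, other: "PairSet") -> "PairSet":
        return PairSet(np.intersect1d(self._packed, other._packed, assume_unique=True))

    __and__ = intersection

    def union(self, other: "PairSet") -> "PairSet":
        return PairSet(np.union1d(self._packed, other._packed))

    __or__ = union

    def difference(self, other: "PairSet") -> "PairSet":
        return PairSet(np.setdiff1d(self._packed, other._packed, assume_unique=True))

    def __iter__(self) -> Iterator[tuple]:
        pb, gb = self._PBITS, self._GBITS
        for code in self._packed.tolist():
            opp = code & 1
            pj = (code >> 1) & self._PMAX
            pi = (code >> (1 + pb)) & self._PMAX
            gj = (code >> (1 + 2 * pb)) & self._GMAX
            gi = (code >> (1 + 2 * pb + gb)) & self._GMAX
            yield ((gi, pi), (gj, pj), "opposite" if opp else "same")

    def renumber(self, mapping: dict[int, int]) -> "PairSet":
        """The same pairs under new genome ids (e.g. to compare alignments
        whose genomes were inserted in different orders)."""
        p = self._packed
        if p.size == 0:
            return PairSet()
        pb, gb = self._PBITS, self._GBITS
        opp = p & 1
        pj = (p >> 1) & self._PMAX
        pi = (p >> (1 + pb)) & self._PMAX
        gj = (p >> (1 + 2 * pb)) & self._GMAX
        gi = (p >> (1 + 2 * pb + gb)) & self._GMAX
        lut = np.zeros(int(max(mapping)) + 1, dtype=np.int64)
        for old, new in mapping.items():
            lut[old] = new
        return PairSet(self.pack_arrays(lut[gi], pi, lut[gj], pj, opp))

    def packed(self) -> np.ndarray:
        return self._packed


# -- operations ------------------------------------------------------------

def validate_alignment(a: GenomeAlignment) -> list[str]:
    """Every invariant violation in ``a`` (empty list when valid).

    Checks: per-block equal row lengths, no all-gap columns, gap-free
    single-row blocks, no duplicated genome within a block, coordinate
    bounds and coordinate/text consistency, and per-genome coverage that is
    complete and non-overlapping.  All violations are collected; nothing
    raises.
    """
    violations: list[str] = []
    ids = [g.genome_id for g in a.genomes]
    if sorted(ids) != list(range(1, len(ids) + 1)):
        violations.append(f"genome ids not contiguous from 1: {sorted(ids)}")
    lengths = {g.genome_id: g.total_length for g in a.genomes}
    intervals: dict[int, list[tuple[int, int, int]]] = {gid: [] for gid in ids}

    for bi, block in enumerate(a.blocks):
        if not block.entries:
            violations.append(f"block {bi}: no entries")
            continue
        width = len(block.entries[0].text)
        seen: set[int] = set()
        texts = []
        for e in block.entries:
            if e.genome_id in seen:
                violations.append(f"block {bi}: duplicate genome {e.genome_id}")
            seen.add(e.genome_id)
            if len(e.text) != width:
                violations.append(
                    f"block {bi} genome {e.genome_id}: unequal text length "
                    f"{len(e.text)} != {width}")
                continue
            texts.append(e.text)
            if e.is_empty:
                if e.nongap_length:
                    violations.append(
                        f"block {bi} genome {e.genome_id}: empty entry with sequence")
                continue
            n = e.nongap_length
            if n != e.end - e.start + 1:
                violations.append(
                    f"block {bi} genome {e.genome_id}: {n} non-gap characters "
                    f"vs coordinates {e.start}-{e.end}")
            if e.strand not in "+-":
                violations.append(f"block {bi} genome {e.genome_id}: bad strand {e.strand!r}")
            if e.genome_id in lengths:
                if not (1 <= e.start <= e.end <= lengths[e.genome_id]):
                    violations.append(
                        f"block {bi} genome {e.genome_id}: coordinates "
                        f"{e.start}-{e.end} out of bounds")
                intervals[e.genome_id].append((e.start, e.end, bi))
            else:
                violations.append(f"block {bi}: unknown genome {e.genome_id}")
        if texts and len(texts) == len(block.entries):
            mat = np.vstack([seq_codes(t) for t in texts])
            if bool(((mat == GAP_CODE).all(axis=0)).any()):
                violations.append(f"block {bi}: all-gap column")
        nonempty = [e for e in block.entries if not e.is_empty]
        if len(nonempty) == 1 and GAP in nonempty[0].text:
            violations.append(f"block {bi}: single-entry block contains gaps")

    for gid in ids:
        ivs = sorted(intervals[gid])
        expected = 1
        for s, e, bi in ivs:
            if s < expected:
                violations.append(
                    f"genome {gid}: overlapping coverage at {s}-{e} (block {bi})")
            elif s > expected:
                violations.append(
                    f"genome {gid}: coverage gap {expected}-{s - 1}")
            expected = max(expected, e + 1)
        if lengths.get(gid) is not None and expected != lengths[gid] + 1 and not (
                lengths[gid] == 0 and expected == 1):
            if not any(v.startswith(f"genome {gid}: coverage gap") or
                       v.startswith(f"genome {gid}: overlapping") for v in violations):
                violations.append(
                    f"genome {gid}: coverage ends at {expected - 1}, "
                    f"genome length {lengths[gid]}")
    return violations


def require_valid(a: GenomeAlignment) -> None:
    violations = validate_alignment(a)
    if violations:
        raise ValidationError(violations[0])


def aligned_pairs(a: GenomeAlignment, validate: bool = True) -> PairSet:
    """All aligned residue pairs of ``a`` as a :class:`PairSet`.

    For every column and every unordered genome pair with non-gap
    characters in that column, the pair of forward-strand positions is
    emitted with orientation "same" iff the two strands agree.
    """
    if validate:
        require_valid(a)
    chunks = []
    for block in a.blocks:
        if len(block.entries) < 2:
            continue
        rows = [(e, *e.positions()) for e in block.entries]
        for i in range(len(rows)):
            ei, mi, pi = rows[i]
            for j in range(i + 1, len(rows)):
                ej, mj, pj = rows[j]
                m = mi & mj
                if not m.any():
                    continue
                opp = 0 if ei.strand == ej.strand else 1
                chunks.append(PairSet.pack_arrays(
                    np.full(int(m.sum()), ei.genome_id), pi[m],
                    np.full(int(m.sum()), ej.genome_id), pj[m],
                    np.full(int(m.sum()), opp)))
    if not chunks:
        return PairSet()
    return PairSet(np.concatenate(chunks))


def extract_genome_sequence(a: GenomeAlignment, genome_id: int) -> str:
    """The original genome sequence, rebuilt losslessly from the alignment."""
    a.genome(genome_id)  # raises KeyError when unknown
    parts = []
    for block in a.blocks:
        e = block.entry(genome_id)
        if e is not None and not e.is_empty:
            parts.append((e.start, e.forward_sequence()))
    parts.sort(key=lambda p: p[0])
    return "".join(seq for _, seq in parts)
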