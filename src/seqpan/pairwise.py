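"""Global pairwise alignment with affine gap costs (banded Gotoh DP).

The band is defined on the diagonal offset j - i and always contains both
the origin and the terminal diagonal.  When the optimal traceback touches a
band edge the band is doubled and the alignment recomputed, so a returned
alignment is always optimal (a band covering the whole matrix is plain
unbanded Gotoh).  A gap run of length L costs ``gap_open + L * gap_extend``.

Scoring is case-insensitive.  ``N`` and every other non-ACGT character
mismatch everything, including themselves: delimiter runs can therefore
never be rewarded for aligning to one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import GAP, GAP_CODE, AlignmentError, seq_codes

NEG = -(1 << 30)

# character class codes: A,C,G,T -> 0..3, everything else (N, IUPAC, ...) -> 4+
_CLASS = np.full(256, 4, dtype=np.int16)
for _i, _ch in enumerate("ACGT"):
    _CLASS[ord(_ch)] = _i
    _CLASS[ord(_ch.lower())] = _i


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1

    def gap_cost(self, length: int) -> int:
        return self.gap_open + self.gap_extend * length if length else 0


DEFAULT_SCORING = Scoring()


def _classes(seq: str) -> np.ndarray:
    return _CLASS[seq_codes(seq)]


def score_alignment(text_a: str, text_b: str, scoring: Scoring = DEFAULT_SCORING) -> int:
    """Affine score of an existing alignment (two equal-length gapped rows)."""
    if len(text_a) != len(text_b):
        raise ValueError("aligned rows differ in length")
    if not text_a:
        return 0
    ca, cb = seq_codes(text_a), seq_codes(text_b)
    ga, gb = ca == GAP_CODE, cb == GAP_CODE
    both = ~ga & ~gb
    cla, clb = _CLASS[ca], _CLASS[cb]
    matches = int(np.sum(both & (cla == clb) & (cla < 4)))
    mismatches = int(both.sum()) - matches
    score = matches * scoring.match + mismatches * scoring.mismatch

    for g in (ga, gb):
        runs = int(np.sum(g & ~np.concatenate(([False], g[:-1]))))
        score += runs * scoring.gap_open + int(g.sum()) * scoring.gap_extend
    return score


def global_align(seq_a: str, seq_b: str,
                 scoring: Scoring = DEFAULT_SCORING,
                 band_width: int = 64,
                 max_cells: int = 30_000_000) -> tuple[int, str, str]:
    """Optimal global alignment of two sequences.

    Returns ``(score, aligned_a, aligned_b)``.  Raises
    :class:`AlignmentError` when the required DP band would exceed
    ``max_cells`` cells before the traceback fits inside it.
    """
    m, n = len(seq_a), len(seq_b)
    if m == 0 and n == 0:
        return 0, "", ""
    if m == 0:
        return scoring.gap_cost(n), GAP * n, seq_b
    if n == 0:
        return scoring.gap_cost(m), seq_a, GAP * m

    w = max(1, band_width, abs(n - m) // 2 + 1)
    while True:
        lo = min(0, n - m) - w
        hi = max(0, n - m) + w
        lo = max(lo, -m)
        hi = min(hi, n)
        full = lo == -m and hi == n
        if (m + 1) * (hi - lo + 1) > max_cells:
            raise AlignmentError(
                f"alignment band exhausted for sequences of length {m} and {n}; "
                "consider an external alignment backend")
        result = _banded_gotoh(seq_a, seq_b, scoring, lo, hi, full)
        if result is not None:
            return result
        w *= 2


def _banded_gotoh(seq_a, seq_b, scoring, lo, hi, full):
    """One banded DP + traceback pass; None when the path hits a band edge."""
    m, n = len(seq_a), len(seq_b)
    W = hi - lo + 1
    go, ge = scoring.gap_open, scoring.gap_extend
    cla = _classes(seq_a)
    clb = _classes(seq_b)
    sub_match, sub_mis = scoring.match, scoring.mismatch

    H = np.full((m + 1, W), NEG, dtype=np.int32)
    f_prev = np.full(W, NEG, dtype=np.int64)
    idx = np.arange(W, dtype=np.int64)

    # row 0: j runs 0..min(n, hi); c = j - lo
    j_hi0 = min(n, hi)
    c0 = -lo
    H[0, c0] = 0
    if j_hi0 >= 1:
        js = np.arange(1, j_hi0 + 1)
        H[0, js - lo] = go + ge * js

    for i in range(1, m + 1):
        jmin = max(0, i + lo)
        jmax = min(n, i + hi)
        cmin = jmin - i - lo
        cmax = jmax - i - lo
        row_valid = (idx >= cmin) & (idx <= cmax)
        js = idx + i + lo  # actual j per slot

        # diagonal: H[i-1] at same slot; requires j >= 1
        diag = H[i - 1].astype(np.int64) + np.where(
            (clb[np.clip(js - 1, 0, n - 1)] == cla[i - 1]) & (cla[i - 1] < 4),
            sub_match, sub_mis)
        diag[js < 1] = NEG

        # vertical (gap in b): from (i-1, j) = slot c+1 of previous row
        h_up = np.concatenate((H[i - 1, 1:].astype(np.int64), [NEG]))
        f_up = np.concatenate((f_prev[1:], [NEG]))
        Frow = np.maximum(f_up + ge, h_up + go + ge)
        Frow[~row_valid] = NEG

        h0 = np.maximum(diag, Frow)
        h0[~row_valid] = NEG

        # horizontal (gap in a) via prefix scan over this row
        t = h0 - ge * idx
        run = np.concatenate(([NEG], np.maximum.accumulate(t)[:-1]))
        Erow = run + ge * idx + go
        Erow[~row_valid] = NEG
        np.clip(Erow, NEG, None, out=Erow)

        Hrow = np.maximum(h0, Erow)
        Hrow[~row_valid] = NEG
        np.clip(Hrow, NEG, None, out=Hrow)
        H[i] = Hrow
        f_prev = Frow

    c_end = n - m - lo
    score = int(H[m, c_end])
    if score <= NEG // 2:
        return None  # band disconnected (cannot normally happen)

    # traceback by recomputation
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    touched = False
    while i > 0 or j > 0:
        c = j - i - lo
        if not full and ((c == 0 and i + lo > 0) or (c == W - 1 and i + hi < n)):
            touched = True
        h = int(H[i, c])
        stepped = False
        if i > 0 and j > 0:
            s = sub_match if (cla[i - 1] == clb[j - 1] and cla[i - 1] < 4) else sub_mis
            cp = j - 1 - (i - 1) - lo
            if 0 <= cp < W and int(H[i - 1, cp]) + s == h:
                out_a.append(seq_a[i - 1])
                out_b.append(seq_b[j - 1])
                i -= 1
                j -= 1
                stepped = True
        if not stepped:
            # vertical gap run: H[i,j] == H[i-l,j] + go + ge*l
            l = 1
            while i - l >= 0:
                cp = j - (i - l) - lo
                if cp >= W or cp < 0:
                    break
                prev = int(H[i - l, cp])
                if prev > NEG // 2 and prev + go + ge * l == h:
                    for t in range(l):
                        out_a.append(seq_a[i - 1 - t])
                        out_b.append(GAP)
                    i -= l
                    stepped = True
                    break
                l += 1
        if not stepped:
            l = 1
            while j - l >= 0:
                cp = j - l - i - lo
                if cp < 0 or cp >= W:
                    break
                prev = int(H[i, cp])
                if prev > NEG // 2 and prev + go + ge * l == h:
                    for t in range(l):
                        out_a.append(GAP)
                        out_b.append(seq_b[j - 1 - t])
                    j -= l
                    stepped = True
                    break
                l += 1
        if not stepped:  # pragma: no cover - would indicate a DP bug
            raise AlignmentError("traceback failed")

    if touched and not full:
        return None
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))
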