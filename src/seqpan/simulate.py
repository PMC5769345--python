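"""Ground-truth synthetic genomes.

Genomes are derived independently from one random ancestor (a star
phylogeny): large deletions, translocations, inversions, small indels and
substitutions are applied per genome while every surviving ancestor base's
position and orientation are tracked, which yields the exact aligned-pair
truth between every pair of genomes.  Everything is deterministic given the
model seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import PairSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MutationModel:
    """Per-genome mutation process applied to the ancestor.

    Rates are per ancestor base; indel lengths are geometric with the given
    mean; structural event lengths are drawn uniformly from their ranges.
    The large-deletion cap of 7000 bp is roughly the longest bacterial gene
    a single event should be able to excise.
    """

    substitution_rate: float = 0.01
    indel_rate: float = 0.001
    indel_mean_length: float = 3.0
    inversions: int = 1
    inversion_length: tuple[int, int] = (100, 1000)
    translocations: int = 1
    translocation_length: tuple[int, int] = (100, 1000)
    large_deletions: int = 1
    max_deletion_length: int = 7000
    seed: int | None = None

    def __post_init__(self):
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for lo, hi in (self.inversion_length, self.translocation_length):
            if lo < 1 or hi < lo:
                raise ValueError("event length ranges must be >= 1 and ordered")
        if self.indel_mean_length < 1:
            raise ValueError("indel mean length must be >= 1")


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _rand_segment(rng, n: int, lo: int, hi: int) -> tuple[int, int]:
    hi = min(hi, n - 1)  # an event may never consume the whole sequence
    if lo > hi:
        raise ValueError(
            f"event length {lo} exceeds sequence length {n}")
    length = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, n - length + 1))
    return start, length


def _evolve(ancestor: np.ndarray, model: MutationModel, rng):
    codes = ancestor.copy()
    anc = np.arange(1, ancestor.size + 1, dtype=np.int64)
    ori = np.ones(ancestor.size, dtype=np.int8)

    def apply(perm_codes, perm_anc, perm_ori):
        nonlocal codes, anc, ori
        codes, anc, ori = perm_codes, perm_anc, perm_ori

    for _ in range(model.large_deletions):
        s, ln = _rand_segment(rng, codes.size, 1, model.max_deletion_length)
        apply(np.delete(codes, slice(s, s + ln)),
              np.delete(anc, slice(s, s + ln)),
              np.delete(ori, slice(s, s + ln)))

    for _ in range(model.translocations):
        s, ln = _rand_segment(rng, codes.size, *model.translocation_length)
        seg = slice(s, s + ln)
        seg_c, seg_a, seg_o = codes[seg].copy(), anc[seg].copy(), ori[seg].copy()
        rc = np.delete(codes, seg)
        ra = np.delete(anc, seg)
        ro = np.delete(ori, seg)
        t = int(rng.integers(0, rc.size + 1))
        apply(np.insert(rc, t, seg_c), np.insert(ra, t, seg_a),
              np.insert(ro, t, seg_o))

    for _ in range(model.inversions):
        s, ln = _rand_segment(rng, codes.size, *model.inversion_length)
        seg = slice(s, s + ln)
        codes[seg] = (3 - codes[seg])[::-1]
        anc[seg] = anc[seg][::-1]
        ori[seg] = -ori[seg][::-1]

    if model.indel_rate > 0:
        n_events = int(rng.binomial(codes.size, model.indel_rate))
        positions = np.sort(rng.integers(0, codes.size, n_events))[::-1]
        for p in positions:
            p = int(p)
            ln = int(rng.geometric(1.0 / model.indel_mean_length))
            if rng.random() < 0.5:  # insertion of novel sequence
                ins = rng.integers(0, 4, ln).astype(codes.dtype)
                codes = np.insert(codes, p, ins)
                anc = np.insert(anc, p, np.zeros(ln, dtype=np.int64))
                ori = np.insert(ori, p, np.ones(ln, dtype=np.int8))
            else:
                ln = min(ln, codes.size - p)
                if ln <= 0 or ln >= codes.size:
                    continue
                codes = np.delete(codes, slice(p, p + ln))
                anc = np.delete(anc, slice(p, p + ln))
                ori = np.delete(ori, slice(p, p + ln))

    if model.substitution_rate > 0:
        mask = rng.random(codes.size) < model.substitution_rate
        shift = rng.integers(1, 4, int(mask.sum())).astype(codes.dtype)
        codes[mask] = (codes[mask] + shift) % 4

    return codes, anc, ori


def truth_pairs(lineages: list[tuple[np.ndarray, np.ndarray]]) -> PairSet:
    """Exact aligned-pair truth from per-genome (ancestor-position,
    orientation) arrays; genome ids are 1-based list positions."""
    chunks = []
    filtered = []
    for anc, ori in lineages:
        keep = anc > 0
        filtered.append((anc[keep], ori[keep],
                         np.flatnonzero(keep).astype(np.int64) + 1))
    for i in range(len(filtered)):
        ai, oi, pi = filtered[i]
        for j in range(i + 1, len(filtered)):
            aj, oj, pj = filtered[j]
            _, ii, jj = np.intersect1d(ai, aj, assume_unique=True,
                                       return_indices=True)
            if ii.size == 0:
                continue
            opposite = (oi[ii].astype(np.int16) * oj[jj].astype(np.int16)) < 0
            chunks.append(PairSet.pack_arrays(
                np.full(ii.size, i + 1), pi[ii],
                np.full(ii.size, j + 1), pj[jj],
                opposite.astype(np.int64)))
    if not chunks:
        return PairSet()
    return PairSet(np.concatenate(chunks))


def simulate_genomes(ancestor_length: int, n_genomes: int,
                     model: MutationModel | None = None):
    """Simulate related genomes with a known true alignment.

    Returns ``(genomes, truth)``: the genome sequences (list of strings,
    genome ids 1..n in list order) and the exact :class:`PairSet` of
    homologous position pairs, orientation-aware through inversions.
    """
    model = model or MutationModel()
    rng = np.random.default_rng(model.seed)
    ancestor = rng.integers(0, 4, ancestor_length).astype(np.uint8)
    genomes = []
    lineages = []
    for _ in range(n_genomes):
        codes, anc, ori = _evolve(ancestor, model, rng)
        genomes.append(_codes_to_str(codes))
        lineages.append((anc, ori))
    return genomes, truth_pairs(lineages)
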