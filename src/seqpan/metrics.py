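"""Alignment comparison metrics and fragmentation statistics.

Precision, recall and F-score are computed over aligned residue pairs with
the intersection enumerated exactly (no sampling); a pair only counts when
its orientation matches.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .datamodel import GenomeAlignment, PairSet


class PairMetrics(NamedTuple):
    precision: float
    recall: float
    f_score: float


def pair_metrics(truth: PairSet, predicted: PairSet) -> PairMetrics:
    """Precision/recall/F over aligned pairs.

    Conventions for empty denominators: an empty prediction has precision
    1, an empty truth has recall 1, and F of (0, 0) is 0.
    """
    tp = int(np.intersect1d(truth.packed(), predicted.packed(),
                            assume_unique=True).size)
    precision = tp / len(predicted) if len(predicted) else 1.0
    recall = tp / len(truth) if len(truth) else 1.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return PairMetrics(precision, recall, f)


class FragmentationStats(NamedTuple):
    total_alignment_length: int
    mean_sequences_per_lcb: float
    n_short_lcbs: int
    n_short_single_lcbs: int


def fragmentation_stats(a: GenomeAlignment, short_len: int = 10) -> FragmentationStats:
    """Total alignment length, mean rows per LCB, and counts of short
    (< short_len columns) LCBs, overall and single-sequence only."""
    if not a.blocks:
        return FragmentationStats(0, 0.0, 0, 0)
    total = sum(b.length for b in a.blocks)
    mean = sum(len(b.entries) for b in a.blocks) / len(a.blocks)
    short = [b for b in a.blocks if b.length < short_len]
    short_single = [b for b in short if len(b.entries) == 1]
    return FragmentationStats(total, mean, len(short), len(short_single))
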