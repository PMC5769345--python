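import numpy as np
import pytest

from seqpan.datamodel import Block, GenomeAlignment, GenomeRecord, SequenceEntry


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_alignment(blocks, lengths):
    """GenomeAlignment from blocks and {genome_id: total_length}."""
    genomes = [GenomeRecord(gid, f"g{gid}", [(f"g{gid}", ln)])
               for gid, ln in sorted(lengths.items())]
    return GenomeAlignment(genomes, blocks)


def entry(gid, start, end, strand, text):
    return SequenceEntry(gid, start, end, strand, text)


def block(*entries, tag="aligned"):
    return Block(list(entries), tag=tag)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# -- independent affine-gap alignment oracle ---------------------------------
# Plain full-matrix Gotoh written separately from the package's banded
# implementation: the reference for optimal scores on small instances.

def oracle_global_score(a: str, b: str, match=1, mismatch=-1,
                        gap_open=-4, gap_extend=-1) -> int:
    ACGT = "ACGT"

    def sub(x, y):
        x, y = x.upper(), y.upper()
        if x in ACGT and x == y:
            return match
        return mismatch

    m, n = len(a), len(b)
    NEG = -10 ** 9
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consume a)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consume b)
    M[0][0] = 0
    for i in range(1, m + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, n + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + sub(a[i - 1], b[j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                          X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                          Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open + gap_extend)
    return max(M[m][n], X[m][n], Y[m][n])
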