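"""Shared fixtures and independent oracles.

The oracles here are deliberately written from scratch (literal codon
table, quadratic Gotoh dynamic program, exhaustive frame scans) so they
share no code path with the package implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from paleoscan.synthetic_data import SimulationConfig, simulate_genome

# ---------------------------------------------------------------------------
# Independent translation oracle: literal standard codon table
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_ORACLE = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}

_RC = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp_oracle(dna: str) -> str:
    return "".join(_RC[c] for c in reversed(dna))


def translate_oracle(dna: str, frame: int) -> str:
    """Per-codon lookup translation of one frame; codons with N give X."""
    if frame < 0:
        dna = revcomp_oracle(dna)
    off = abs(frame) - 1
    out = []
    for i in range(off, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append("X" if "N" in codon else CODON_ORACLE[codon])
    return "".join(out)


def orf_oracle(dna: str, min_aa: int) -> set[tuple[int, int]]:
    """Exhaustive scan: all (frame, aa length) of maximal stop-free
    segments >= min_aa across the six frames."""
    out = set()
    for frame in (1, 2, 3, -1, -2, -3):
        for segment in translate_oracle(dna, frame).split("*"):
            if len(segment) >= min_aa:
                out.add((frame, len(segment)))
    return out


# ---------------------------------------------------------------------------
# Independent local-alignment oracle: quadratic affine-gap DP
# ---------------------------------------------------------------------------

_B62_ALPHA = "ARNDCQEGHILKMFPSTWYVBZX*"
# BLOSUM62, row-major over the alphabet above (standard NCBI values)
_B62_ROWS = """
 4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0 -2 -1  0 -4
-1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3 -1  0 -1 -4
-2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3  3  0 -1 -4
-2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3  4  1 -1 -4
 0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1 -3 -3 -2 -4
-1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2  0  3 -1 -4
-1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2  1  4 -1 -4
 0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3 -1 -2 -1 -4
-2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3  0  0 -1 -4
-1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3 -3 -3 -1 -4
-1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1 -4 -3 -1 -4
-1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2  0  1 -1 -4
-1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1 -3 -1 -1 -4
-2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1 -3 -3 -1 -4
-1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2 -2 -1 -2 -4
 1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2  0  0  0 -4
 0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0 -1 -1  0 -4
-3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3 -4 -3 -2 -4
-2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1 -3 -2 -1 -4
 0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4 -3 -2 -1 -4
-2 -1  3  4 -3  0  1 -1  0 -3 -4  0 -3 -3 -2  0 -1 -4 -3 -3  4  1 -1 -4
-1  0  0  1 -3  3  4 -2  0 -3 -3  1 -1 -3 -1  0 -1 -3 -2 -2  1  4 -1 -4
 0 -1 -1 -1 -2 -1 -1 -1 -1 -1 -1 -1 -1 -1 -2  0  0 -2 -1 -1 -1 -1 -1 -4
-4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4  1
"""
_B62 = np.array([[int(x) for x in row.split()] for row in _B62_ROWS.strip().splitlines()])
_B62_INDEX = {c: i for i, c in enumerate(_B62_ALPHA)}


def blosum62_score(a: str, b: str) -> int:
    return int(_B62[_B62_INDEX[a], _B62_INDEX[b]])


def sw_local_score(
    a: str,
    b: str,
    gap_open: int = 11,
    gap_extend: int = 1,
    match: int | None = None,
    mismatch: int | None = None,
) -> float:
    """Optimal local alignment score with affine gaps (a gap of length g
    costs gap_open + gap_extend * g), by the full quadratic Gotoh DP.

    Scores come from BLOSUM62 unless match/mismatch are given.
    """
    if not a or not b:
        return 0.0
    oe = gap_open + gap_extend
    e = gap_extend
    n = len(b)
    if match is None:
        ai = np.array([_B62_INDEX[c] for c in a])
        bi = np.array([_B62_INDEX[c] for c in b])
        score_rows = _B62[np.ix_(ai, bi)].astype(float)
    else:
        barr = np.array(list(b))
        score_rows = np.array(
            [np.where(barr == c, float(match), float(mismatch)) for c in a]
        )
    neg = -1e18
    M_prev = np.full(n + 1, neg)
    Ix_prev = np.full(n + 1, neg)
    Iy_prev = np.full(n + 1, neg)
    M_prev[:] = neg
    best = 0.0
    ks = np.arange(n + 1, dtype=float)
    for i in range(1, len(a) + 1):
        M = np.full(n + 1, neg)
        diag = np.maximum.reduce(
            [np.zeros(n), M_prev[:-1], Ix_prev[:-1], Iy_prev[:-1]]
        )
        M[1:] = diag + score_rows[i - 1]
        Ix = np.maximum(M_prev - oe, Ix_prev - e)
        run = np.maximum.accumulate(M + e * ks)
        # Iy[j] = max_{k<j} M[k] - (open + extend*(j-k)), via a running max
        Iy = np.full(n + 1, neg)
        Iy[1:] = run[:-1] - (oe - e) - e * ks[1:]
        best = max(best, float(M.max()))
        M_prev, Ix_prev, Iy_prev = M, Ix, Iy
    return best


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_sim():
    """A small genome with five viral integrations (d=0.1) and decoys."""
    config = SimulationConfig(
        seed=11,
        contig_count=2,
        contig_length=60_000,
        n_viral_insertions=5,
        divergence=0.1,
        decoys_per_category={"host": 2, "TE": 2, "retroviral": 2},
    )
    return simulate_genome(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
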