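"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles (full dynamic
programming over every cell, exhaustive placement enumeration) without
sharing any code with the production paths they check.
"""

from __future__ import annotations

import numpy as np

NEG = -1.0e12


def glocal_affine_score(ref: str, read: str, match: int = 5, mismatch: int = 4,
                        gap_open: int = 25, gap_extend: int = 1) -> float:
    """Full-DP affine-gap score, read-global / reference-local.

    Gap cost convention: cost(k) = gap_open + k * gap_extend. The reference
    may overhang the read freely on both sides; every read base must be
    aligned or paid for as an insertion. Computes all three Gotoh state
    matrices over every cell.
    """
    n, m = len(ref), len(read)
    refa = np.frombuffer(ref.encode(), dtype=np.uint8)
    reada = np.frombuffer(read.encode(), dtype=np.uint8)
    open_cost = gap_open + gap_extend

    M = np.zeros(n + 1)            # row 0: any reference prefix skipped free
    Ix = np.full(n + 1, NEG)       # read base(s) aligned to a gap
    Iy = np.full(n + 1, NEG)       # reference base(s) aligned to a gap
    idx = np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        sub = np.where(refa == reada[i - 1], float(match), float(-mismatch))
        best_prev = np.maximum(np.maximum(M, Ix), Iy)
        newM = np.full(n + 1, NEG)
        newM[1:] = best_prev[:-1] + sub
        newIx = np.maximum(np.maximum(M, Iy) - open_cost, Ix - gap_extend)
        # Iy[j] = max_{k<j} (best-of-M/Ix at k) - gap_open - (j-k)*gap_extend,
        # computed with a running prefix maximum over shifted scores
        base = np.maximum(newM, newIx) + idx * gap_extend
        prefix = np.maximum.accumulate(base[:-1])
        newIy = np.full(n + 1, NEG)
        newIy[1:] = prefix - gap_open - idx[1:] * gap_extend
        M, Ix, Iy = newM, newIx, newIy
    # trailing reference is free, trailing read gaps are not: end in M or Ix
    return float(max(M.max(), Ix.max()))


def mh_by_placement_enumeration(seq: str, start: int, end: int) -> int:
    """Microhomology length as (number of sequence-equivalent deletion
    placements) - 1, found by deleting the same number of bases at every
    possible position and comparing the resulting strings."""
    k = end - start
    target = seq[:start] + seq[end:]
    count = sum(
        1 for s in range(len(seq) - k + 1)
        if seq[:s] + seq[s + k:] == target
    )
    return count - 1


def random_alignment_instance(rng: np.random.Generator, max_len: int = 200):
    """A (ref, read) pair: the read is a mutated reference window or, one
    time in ten, unrelated sequence."""
    bases = np.array(list("ACGT"))
    n = int(rng.integers(30, max_len + 1))
    ref = "".join(rng.choice(bases, size=n))
    if rng.random() < 0.1:
        read = "".join(rng.choice(bases, size=int(rng.integers(10, max_len + 1))))
        return ref, read
    lo = int(rng.integers(0, n // 2))
    hi = int(rng.integers(lo + 10, n + 1))
    read = list(ref[lo:hi])
    for _ in range(int(rng.integers(0, 6))):
        if len(read) < 12:
            break
        p = int(rng.integers(1, len(read) - 1))
        kind = rng.random()
        if kind < 0.5:
            read[p] = str(rng.choice(bases))
        elif kind < 0.75:
            del read[p:p + int(rng.integers(1, 6))]
        else:
            read[p:p] = rng.choice(bases, size=int(rng.integers(1, 6))).tolist()
    return ref, "".join(read)
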