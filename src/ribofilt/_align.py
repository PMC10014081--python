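"""Numba alignment kernels: exact affine-gap Smith-Waterman raw scores and
ungapped read placement.

Conventions
-----------
* Scores are integers. A gap of length k costs ``gap_open + k * gap_extend``
  (both penalties are non-positive), i.e. opening a single-base gap costs
  ``gap_open + gap_extend`` — the BLAST parameterisation.
* N (code 4) never matches anything, including another N.
* These are exact dynamic programs, not seeded heuristics: the raw score is
  the maximum over all local alignments.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sw_score(q: np.ndarray, t: np.ndarray, match: int, mismatch: int,
             gap_open: int, gap_extend: int) -> int:
    """Best local alignment score of query codes vs target codes (one strand)."""
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, -10**9, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        diag = H[0]          # H[i-1][0]
        H[0] = 0
        E = -10**9           # gap consuming target, recomputed left-to-right
        for j in range(1, m + 1):
            s = match if (qi == t[j - 1] and qi != 4) else mismatch
            E = max(H[j - 1] + gap_open + gap_extend, E + gap_extend)
            F[j] = max(H[j] + gap_open + gap_extend, F[j] + gap_extend)
            h = diag + s
            if E > h:
                h = E
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def best_ungapped_placement(q: np.ndarray, t: np.ndarray,
                            match: int, mismatch: int) -> tuple[int, int]:
    """(score, offset) of the best full-length ungapped placement of q on t.

    Offsets run over every position where q fits entirely inside t; ties go
    to the smallest offset. Requires len(t) >= len(q).
    """
    n = q.shape[0]
    m = t.shape[0]
    best = -10**9
    best_off = 0
    for off in range(m - n + 1):
        s = 0
        for i in range(n):
            if q[i] == t[off + i] and q[i] != 4:
                s += match
            else:
                s += mismatch
        if s > best:
            best = s
            best_off = off
    return best, best_off


@njit(cache=True)
def best_overlap_placement(q: np.ndarray, t: np.ndarray, match: int,
                           mismatch: int, min_overlap: int) -> tuple[int, int]:
    """(score, offset) of the best ungapped placement of q on t, allowing
    the query to overhang either template end by up to len(q) - min_overlap.

    The score is computed over the overlapping columns only; ties go to the
    smallest offset (which may be negative).
    """
    n = q.shape[0]
    m = t.shape[0]
    best = -10**9
    best_off = -(n - min_overlap)
    for off in range(-(n - min_overlap), m - min_overlap + 1):
        lo = 0 if off >= 0 else -off
        hi = n if off + n <= m else m - off
        s = 0
        for i in range(lo, hi):
            if q[i] == t[off + i] and q[i] != 4:
                s += match
            else:
                s += mismatch
        if s > best:
            best = s
            best_off = off
    return best, best_off


def warmup() -> None:
    """Trigger JIT compilation once (keeps first-call latency out of timings)."""
    a = np.array([0, 1, 2, 3], dtype=np.uint8)
    sw_score(a, a, 2, -3, -5, -2)
    best_ungapped_placement(a, a, 2, -3)
    best_overlap_placement(a, a, 2, -3, 2)
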