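"""Brute-force pure-Python Smith-Waterman oracle used by the tests.

Full O(nm) affine-gap dynamic program over three explicit matrices; a gap
of length k costs gap_open + k * gap_extend. Kept deliberately independent
of the package's alignment kernels.
"""

NEG = float("-inf")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def sw_oracle(q: str, t: str, match: int, mismatch: int,
              gap_open: int, gap_extend: int) -> int:
    """Best local alignment score of q vs t (single strand)."""
    n, m = len(q), len(t)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            s = match if (qi == t[j - 1] and qi != "N") else mismatch
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best = h
    return best


def sw_oracle_both_strands(q: str, t: str, match: int, mismatch: int,
                           gap_open: int, gap_extend: int) -> int:
    return max(
        sw_oracle(q, t, match, mismatch, gap_open, gap_extend),
        sw_oracle(revcomp(q), t, match, mismatch, gap_open, gap_extend),
    )
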