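"""Low-level sequence utilities shared across modules.

Sequences are plain upper-case DNA strings over {A, C, G, T, N}. RNA input
(U) is mapped to T at ingest; IUPAC ambiguity codes collapse to N.
"""

from __future__ import annotations

import re

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_AMBIGUITY = str.maketrans({c: "N" for c in "RYSWKMBDHV"})
_VALID = re.compile(r"^[ACGTN]*$")

# integer codes used by the numba alignment kernels; N = 4 never matches
_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i


def normalize(seq: str, *, context: str = "sequence") -> str:
    """Upper-case, U->T, ambiguity codes -> N; reject anything else."""
    s = seq.upper().translate(_RNA_TO_DNA).translate(_AMBIGUITY)
    if not _VALID.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"{context}: non-nucleotide characters {bad!r}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN as uint8 codes 0-4 for the alignment kernels."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return codes


def percent_identity(query: str, target: str, mode: str = "HW") -> float:
    """Percent identity of the best alignment of *query* against *target*.

    Identity is matches / alignment columns, end gaps excluded ("HW" infix
    mode aligns the query inside the target without penalising target
    overhangs). Both strands are tried; the better one is reported.
    """
    best = 0.0
    for q in (query, revcomp(query)):
        res = edlib.align(q, target, task="path", mode=mode)
        if res["editDistance"] < 0:
            continue
        matches, columns = _cigar_stats(res["cigar"])
        if columns:
            best = max(best, 100.0 * matches / columns)
    return best


def best_alignment_span(query: str, target: str) -> tuple[float, int, int, str]:
    """(identity, start, end, strand) of the best infix placement of query
    on target; end is exclusive. Used for recovery metrics and binning."""
    best = (-1.0, 0, 0, "+")
    for strand, q in (("+", query), ("-", revcomp(query))):
        res = edlib.align(q, target, task="path", mode="HW")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        matches, columns = _cigar_stats(res["cigar"])
        ident = 100.0 * matches / columns if columns else 0.0
        if ident > best[0]:
            s, e = res["locations"][0]
            best = (ident, s, e + 1, strand)
    return best


def _cigar_stats(cigar: str) -> tuple[int, int]:
    matches = columns = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return matches, columns
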