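"""Per-read best-hit scoring against the two library partitions.

Each read receives the raw local-alignment score of its best hit (either
strand) against the Insecta and Non-Insecta reference sets, the ratio of
Insecta over Non-Insecta scores, and one of four categories mirroring the
ratio-of-scores plot:

* ``I_ONLY``  — hits only in the Insecta library,
* ``I_GT_N``  — hits in both, Insecta score >= Non-Insecta score,
* ``N_GT_I``  — hits in both, Non-Insecta score strictly higher,
* ``NO_I``    — no hit in the Insecta library.

Scores can come from the built-in exact Smith-Waterman scorer or from an
external aligner's tabular output (BLAST outfmt 6); both partitions must be
scored with identical parameters for the ratio to be meaningful. The two
paths are not identical: the internal scorer reports a hit whenever the raw
score reaches ``min_report_score``, whereas an external aligner applies its
own reporting threshold (E-value based for BLAST).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _align
from ._seq import encode, normalize, revcomp
from .reference_library import LibraryPartition, ReferenceSequence


class Category(str, enum.Enum):
    I_ONLY = "I_ONLY"   # region (i):  hit only in Insecta
    I_GT_N = "I_GT_N"   # region (ii): ratio >= 1
    N_GT_I = "N_GT_I"   # region (iii): ratio < 1
    NO_I = "NO_I"       # region (iv): no Insecta hit

    def __str__(self) -> str:  # tidy TSV output
        return self.value


@dataclass(frozen=True)
class ScoringParams:
    """Raw-score alignment parameters (blastn task defaults)."""

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_report_score: int = 50

    def __post_init__(self):
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty >= 0:
            raise ValueError("mismatch_penalty must be negative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if self.min_report_score <= 0:
            raise ValueError("min_report_score must be positive")


@dataclass(frozen=True)
class ScoredRead:
    """A read with its two best-hit scores, ratio, and category."""

    read_id: str
    s_insecta: Optional[float]
    s_non_insecta: Optional[float]

    @property
    def ratio(self) -> Optional[float]:
        if self.s_insecta is None or self.s_non_insecta is None:
            return None
        return self.s_insecta / self.s_non_insecta

    @property
    def category(self) -> Category:
        if self.s_insecta is None:
            return Category.NO_I
        if self.s_non_insecta is None:
            return Category.I_ONLY
        return Category.I_GT_N if self.ratio >= 1.0 else Category.N_GT_I


def best_hit_score(
    read: str,
    library: Iterable[ReferenceSequence],
    params: ScoringParams = ScoringParams(),
) -> Optional[int]:
    """Maximum local-alignment raw score of *read* (either strand) against
    any library sequence; None when below ``min_report_score`` or the
    library is empty (no hit)."""
    if not read:
        raise ValueError("empty read")
    read = normalize(read, context="read")
    fwd = encode(read)
    rev = encode(revcomp(read))
    best = _best_vs_encoded(fwd, rev, [encode(r.sequence) for r in library], params)
    return best if best >= params.min_report_score else None


def _best_vs_encoded(
    fwd: np.ndarray,
    rev: np.ndarray,
    encoded_refs: Sequence[np.ndarray],
    params: ScoringParams,
) -> int:
    best = 0
    for ref in encoded_refs:
        for q in (fwd, rev):
            s = _align.sw_score(
                q, ref, params.match_reward, params.mismatch_penalty,
                params.gap_open, params.gap_extend,
            )
            if s > best:
                best = s
    return best


def score_reads(
    reads: Sequence[tuple[str, str]],
    partition: LibraryPartition,
    params: ScoringParams = ScoringParams(),
) -> list[ScoredRead]:
    """Score every (id, sequence) read against both partitions.

    Identical parameters are applied to both sides; reference sequences are
    encoded once up front.
    """
    if not reads:
        raise ValueError("no reads to score")
    _align.warmup()
    enc_ins = [encode(r.sequence) for r in partition.insecta.values()]
    enc_non = [encode(r.sequence) for r in partition.non_insecta.values()]
    out: list[ScoredRead] = []
    for read_id, seq in reads:
        seq = normalize(seq, context=f"read {read_id!r}")
        fwd = encode(seq)
        rev = encode(revcomp(seq))
        s_i = _best_vs_encoded(fwd, rev, enc_ins, params)
        s_n = _best_vs_encoded(fwd, rev, enc_non, params)
        out.append(
            ScoredRead(
                read_id,
                s_i if s_i >= params.min_report_score else None,
                s_n if s_n >= params.min_report_score else None,
            )
        )
    return out


# --- external aligner (BLAST outfmt 6) support ------------------------------

_OUTFMT6_MIN_COLS = 12
_SCORE_COLUMNS = {"bitscore": 11, "score": 12}


def parse_external_hits(
    source: Union[str, Path, IO[str]],
    library_label: str = "",
    score_column: str = "bitscore",
) -> dict[str, float]:
    """Best score per query from BLAST tabular (outfmt 6) text.

    ``score_column`` selects the standard bitscore (column 12) or a raw
    ``score`` appended as column 13 (``-outfmt "6 std score"``); whichever is
    chosen must be applied identically to both libraries.
    """
    if score_column not in _SCORE_COLUMNS:
        raise ValueError(f"score_column must be one of {sorted(_SCORE_COLUMNS)}")
    col = _SCORE_COLUMNS[score_column]
    close = False
    if isinstance(source, (str, Path)):
        source = open(source)
        close = True
    best: dict[str, float] = {}
    try:
        for lineno, line in enumerate(source, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < max(_OUTFMT6_MIN_COLS, col + 1):
                raise ValueError(
                    f"{library_label or 'hits'} line {lineno}: expected >= "
                    f"{max(_OUTFMT6_MIN_COLS, col + 1)} tab-separated columns, got {len(fields)}"
                )
            try:
                score = float(fields[col])
            except ValueError as exc:
                raise ValueError(
                    f"{library_label or 'hits'} line {lineno}: bad score field {fields[col]!r}"
                ) from exc
            q = fields[0]
            if q not in best or score > best[q]:
                best[q] = score
    finally:
        if close:
            source.close()
    return best


def scored_reads_from_hits(
    read_ids: Iterable[str],
    insecta_hits: dict[str, float],
    non_insecta_hits: dict[str, float],
) -> list[ScoredRead]:
    """Combine two external best-hit maps into ScoredRead records."""
    return [
        ScoredRead(rid, insecta_hits.get(rid), non_insecta_hits.get(rid))
        for rid in read_ids
    ]


# --- TSV round trip ---------------------------------------------------------

def scores_to_frame(scored: Sequence[ScoredRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [s.read_id for s in scored],
            "s_insecta": [s.s_insecta for s in scored],
            "s_non_insecta": [s.s_non_insecta for s in scored],
            "ratio": [s.ratio for s in scored],
            "category": [s.category.value for s in scored],
        }
    )


def write_scores_tsv(scored: Sequence[ScoredRead], path: str | Path) -> None:
    scores_to_frame(scored).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_scores_tsv(path: str | Path) -> list[ScoredRead]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    out = []
    for row in df.itertuples(index=False):
        s_i = None if pd.isna(row.s_insecta) else float(row.s_insecta)
        s_n = None if pd.isna(row.s_non_insecta) else float(row.s_non_insecta)
        out.append(ScoredRead(str(row.read_id), s_i, s_n))
    return out
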