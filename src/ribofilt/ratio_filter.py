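"""Threshold filtration of scored reads and the ratio-of-scores summary.

A read is admitted to assembly when it has a hit only in the Insecta library
(no denominator exists) or when its ratio of Insecta over Non-Insecta scores
clears the threshold — 0.8 by default, a deliberately conservative cut that
only removes reads clearly of non-insect origin, since neither reference set
is exhaustive. Reads without any Insecta hit are always discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .read_scoring import Category, ScoredRead

DEFAULT_THRESHOLD = 0.8


@dataclass(frozen=True)
class FilterConfig:
    """Threshold on the ratio of scores; inclusive (>=) by default."""

    threshold: float = DEFAULT_THRESHOLD
    inclusive: bool = True

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def passes(self, read: ScoredRead) -> bool:
        if read.category is Category.NO_I:
            return False
        if read.category is Category.I_ONLY:
            return True
        r = read.ratio
        return r >= self.threshold if self.inclusive else r > self.threshold


@dataclass(frozen=True)
class FilterSummary:
    """Counts and percentages of kept / below-threshold / no-Insecta reads."""

    n_total: int
    n_kept: int
    n_below: int
    n_no_insecta: int
    pct_kept: float
    pct_below: float
    pct_no_insecta: float

    def as_dict(self) -> dict:
        return asdict(self)


def filter_reads(
    scored: Sequence[ScoredRead], config: FilterConfig = FilterConfig()
) -> tuple[list[str], list[str]]:
    """Partition read ids into (kept, discarded), preserving input order."""
    if not scored:
        raise ValueError("no scored reads")
    kept, discarded = [], []
    for s in scored:
        (kept if config.passes(s) else discarded).append(s.read_id)
    return kept, discarded


def summarize(
    scored: Sequence[ScoredRead], config: FilterConfig = FilterConfig()
) -> FilterSummary:
    """Category counts and percentages (percentages of the total, reported
    at full precision; display rounding is left to the caller)."""
    if not scored:
        raise ValueError("no scored reads")
    n_total = len(scored)
    n_kept = n_below = n_no = 0
    for s in scored:
        if s.category is Category.NO_I:
            n_no += 1
        elif config.passes(s):
            n_kept += 1
        else:
            n_below += 1
    return FilterSummary(
        n_total=n_total,
        n_kept=n_kept,
        n_below=n_below,
        n_no_insecta=n_no,
        pct_kept=100.0 * n_kept / n_total,
        pct_below=100.0 * n_below / n_total,
        pct_no_insecta=100.0 * n_no / n_total,
    )


@dataclass(frozen=True)
class RatioHistogram:
    """Binned defined-ratio counts plus the two special buckets of the
    ratio-of-scores plot: Insecta-only reads (no denominator; the overflow
    band at the top) and reads with no Insecta hit (the band at zero)."""

    edges: tuple[float, ...]          # len = n_bins + 1, over [0, ratio_cap]
    counts: tuple[int, ...]           # per bin; half-open, last bin closed
    insecta_only: int
    no_insecta: int

    @property
    def n_total(self) -> int:
        return sum(self.counts) + self.insecta_only + self.no_insecta


def ratio_histogram(
    scored: Sequence[ScoredRead], n_bins: int, ratio_cap: float
) -> RatioHistogram:
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if ratio_cap <= 1:
        raise ValueError("ratio_cap must exceed 1")
    width = ratio_cap / n_bins
    edges = tuple(i * width for i in range(n_bins + 1))
    counts = [0] * n_bins
    i_only = no_i = 0
    for s in scored:
        if s.category is Category.NO_I:
            no_i += 1
        elif s.category is Category.I_ONLY:
            i_only += 1
        else:
            r = s.ratio
            idx = int(r / width)
            if idx >= n_bins:      # cap value and anything above: last bin
                idx = n_bins - 1
            counts[idx] += 1
    return RatioHistogram(edges, tuple(counts), i_only, no_i)


def write_summary_json(summary: FilterSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.as_dict(), indent=2))


def write_histogram_tsv(hist: RatioHistogram, path: str | Path) -> None:
    rows = [
        {"bin": f"[{lo:g},{hi:g}{']' if i == len(hist.counts) - 1 else ')'}", "count": c}
        for i, (lo, hi, c) in enumerate(zip(hist.edges[:-1], hist.edges[1:], hist.counts))
    ]
    rows.append({"bin": "insecta_only", "count": hist.insecta_only})
    rows.append({"bin": "no_insecta_hit", "count": hist.no_insecta})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
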