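"""COI barcode processing: Sanger read trimming, pair consensus, and
rule-based species assignment.

The mitochondrial cytochrome c oxidase subunit I (COI) gene, amplified with
the universal Folmer primers (658 bp product), is the standard animal DNA
barcode. Forward/reverse Sanger reads are end-trimmed for quality (Q < 30),
anchored at fixed motifs (forward reads start 5'-TTTTGG, reverse reads
5'-GGNTCT), overlapped into a 621 bp consensus (extensible to 699 bp when
both reads reach further), and compared against reference hits to confirm
or revise the morphological species identification. Nucleotide similarity
below 95% delineates distinct species; a revision must beat the
morphological species' identity by more than 2%.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from ._seq import revcomp

# Folmer primer pair (5'->3')
LCO1490 = "GGTCAACAAATCATAAAGATATTGG"
HCO2198 = "TAAACTTCAGGGTGACCAAAAAATCA"

FORWARD_ANCHOR = "TTTTGG"
REVERSE_ANCHOR = "GGNTCT"

DEFAULT_QUALITY_FLOOR = 30
DEFAULT_CONSENSUS_LENGTH = 621
MAX_CONSENSUS_LENGTH = 699
DEFAULT_SPECIES_THRESHOLD = 95.0
DEFAULT_REVISION_MARGIN = 2.0


@dataclass(frozen=True)
class SangerRead:
    direction: str                      # "forward" | "reverse"
    sequence: str
    qualities: Optional[tuple[int, ...]] = None

    def __post_init__(self):
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        if self.qualities is not None:
            object.__setattr__(self, "qualities", tuple(self.qualities))
            if len(self.qualities) != len(self.sequence):
                raise ValueError("qualities length != sequence length")


@dataclass(frozen=True)
class SpeciesCall:
    """A barcode identification with its supporting evidence."""

    status: str    # confirmed | revised | ambiguous_sister_species | genus_only | no_reference
    species: Optional[str]
    genus: Optional[str]
    morphological_id: Optional[str]
    evidence: tuple[tuple[str, float], ...]

    def __post_init__(self):
        if self.status == "genus_only" and (self.genus is None or self.species is not None):
            raise ValueError("genus_only calls carry a genus and no species")
        if self.status in ("confirmed", "revised") and self.species is None:
            raise ValueError(f"{self.status} calls must carry a species")

    @property
    def display_name(self) -> Optional[str]:
        if self.status == "genus_only":
            return f"{self.genus} sp."
        return self.species or self.morphological_id


def _anchor_regex(anchor: str) -> re.Pattern:
    return re.compile("".join("[ACGT]" if c == "N" else c for c in anchor))


def trim_read(
    read: SangerRead,
    quality_floor: int = DEFAULT_QUALITY_FLOOR,
    anchor: Optional[str] = None,
) -> SangerRead:
    """Quality-trim both ends (bases with Q below the floor), then 5'-trim
    to the first occurrence of the direction's anchor motif (N matches any
    base). Idempotent."""
    if anchor is None:
        anchor = FORWARD_ANCHOR if read.direction == "forward" else REVERSE_ANCHOR
    seq, quals = read.sequence, read.qualities
    if quals is not None:
        lo, hi = 0, len(seq)
        while lo < hi and quals[lo] < quality_floor:
            lo += 1
        while hi > lo and quals[hi - 1] < quality_floor:
            hi -= 1
        seq, quals = seq[lo:hi], quals[lo:hi]
    m = _anchor_regex(anchor).search(seq)
    if m is None:
        raise ValueError(f"anchor {anchor} not found in {read.direction} read after quality trim")
    return SangerRead(read.direction, seq[m.start():],
                      quals[m.start():] if quals is not None else None)


@dataclass(frozen=True)
class ConsensusResult:
    """Merged read pair; ``sequence`` is the consensus DNA string."""

    sequence: str
    complete: bool            # reaches the configured consensus length
    overlap_length: int
    overlap_identity: float
    n_disagreements: int

    def __str__(self) -> str:
        return self.sequence


def build_consensus(
    forward: SangerRead,
    reverse: SangerRead,
    min_overlap_identity: float = 98.0,
    min_overlap: int = 20,
    target_length: int = DEFAULT_CONSENSUS_LENGTH,
    max_length: int = MAX_CONSENSUS_LENGTH,
    extend: bool = True,
) -> ConsensusResult:
    """Overlap the trimmed forward read with the reverse-complemented
    reverse read and merge into a consensus.

    The best ungapped overlap (most matching columns; ties to the longer
    overlap) defines the join; its identity must reach
    ``min_overlap_identity`` or the pair is rejected as discordant.
    Disagreements take the higher-quality base, the forward base when
    qualities are absent or tied. The consensus is cut at ``target_length``
    (621) and extended up to ``max_length`` (699) only where both reads
    cover the extra span.
    """
    f, fq = forward.sequence, forward.qualities
    r = revcomp(reverse.sequence)
    rq = reverse.qualities[::-1] if reverse.qualities is not None else None

    best = None   # (matches, overlap, offset)
    max_d = len(f) - min_overlap
    for d in range(0, max_d + 1):
        o = min(len(f) - d, len(r))
        if o < min_overlap:
            continue
        matches = sum(1 for a, b in zip(f[d: d + o], r[:o]) if a == b)
        key = (matches, o, -d)
        if best is None or key > best[0]:
            best = (key, d, o)
    if best is None:
        raise ValueError("reads too short to overlap")
    (_k, d, o) = (best[0], best[1], best[2])
    matches = best[0][0]
    identity = 100.0 * matches / o
    if identity < min_overlap_identity:
        raise ValueError(
            f"read pair discordant: overlap identity {identity:.2f}% "
            f"< {min_overlap_identity}%"
        )

    merged = list(f[:d])
    n_disagree = 0
    for j in range(o):
        a, b = f[d + j], r[j]
        if a == b:
            merged.append(a)
            continue
        n_disagree += 1
        qa = fq[d + j] if fq is not None else None
        qb = rq[j] if rq is not None else None
        if qa is not None and qb is not None and qb > qa:
            merged.append(b)
        else:
            merged.append(a)    # forward wins on ties / absent qualities
    merged.extend(r[o:])
    m = "".join(merged)

    double_covered_end = d + o     # columns covered by both reads: [d, d+o)
    if len(m) >= target_length:
        out_len = target_length
        if extend and double_covered_end > target_length:
            out_len = min(max_length, double_covered_end, len(m))
        out, complete = m[:out_len], True
    else:
        out, complete = m, False
    return ConsensusResult(out, complete, o, identity, n_disagree)


def assign_species(
    morphological_id: Optional[str],
    hits: Sequence[tuple[str, float]],
    species_threshold: float = DEFAULT_SPECIES_THRESHOLD,
    revision_margin: float = DEFAULT_REVISION_MARGIN,
    consensus_length: int = DEFAULT_CONSENSUS_LENGTH,
) -> SpeciesCall:
    """Rule-based validation of a morphological identification against a
    ranked list of (reference species name, percent identity) hits.

    Rules, in order:

    a. no hit reaches ``species_threshold`` and all hit species share one
       genus -> ``genus_only`` ("unknown member of their genus");
    b. the top two hits are different species within one substitution's
       worth of identity (100/consensus_length percent) of each other and
       the morphological species is one of them -> ``ambiguous_sister_species``
       (the morphological identity is retained);
    c. top hit qualifies and matches the morphological species -> ``confirmed``;
    d. top hit qualifies, differs, and beats the morphological species'
       identity by more than ``revision_margin`` -> ``revised``; when the
       morphological species has no reference among the hits the margin is
       taken against the best hit of any other species;
    e. otherwise the evidence cannot overturn morphology ->
       ``ambiguous_sister_species``; with no qualifying hit at all and no
       reference for the morphological species -> ``no_reference``.
    """
    hits = sorted(hits, key=lambda h: -h[1])
    if not hits:
        if morphological_id is None:
            raise ValueError("no hits and no morphological identification")
        return SpeciesCall("no_reference", None, _genus(morphological_id),
                           morphological_id, ())
    evidence = tuple((n, float(i)) for n, i in hits)
    top_name, top_id = hits[0]

    if top_id < species_threshold:
        genera = {_genus(n) for n, _ in hits}
        if len(genera) == 1:
            return SpeciesCall("genus_only", None, genera.pop(), morphological_id, evidence)
        return SpeciesCall("no_reference", None,
                           _genus(morphological_id) if morphological_id else None,
                           morphological_id, evidence)

    one_substitution = 100.0 / consensus_length
    if len(hits) > 1:
        second_name, second_id = hits[1]
        if (second_name != top_name and top_id - second_id <= one_substitution
                and morphological_id in (top_name, second_name)):
            return SpeciesCall("ambiguous_sister_species", None,
                               _genus(morphological_id), morphological_id, evidence)

    if morphological_id is not None and top_name == morphological_id:
        return SpeciesCall("confirmed", top_name, _genus(top_name),
                           morphological_id, evidence)

    morph_ids = [i for n, i in hits if n == morphological_id]
    if morph_ids:
        competing = max(morph_ids)
    else:
        others = [i for n, i in hits if n != top_name]
        competing = max(others) if others else None
    if competing is None or top_id - competing > revision_margin:
        return SpeciesCall("revised", top_name, _genus(top_name),
                           morphological_id, evidence)
    return SpeciesCall("ambiguous_sister_species", None,
                       _genus(morphological_id) if morphological_id else None,
                       morphological_id, evidence)


def _genus(binomial: Optional[str]) -> Optional[str]:
    if not binomial:
        return None
    return binomial.split()[0]
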