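"""Synthetic fixtures: rRNA references with conserved/variable block
architecture, contaminated specimen read sets, and COI amplicon read pairs.

Real rRNA genes interleave blocks that are nearly invariant across distant
taxa (the basis of cross-species probe depletion — and of the read-
classification ambiguity this package addresses) with variable blocks that
carry the taxonomic signal. The generator emulates exactly that structure:
references are uniform-random sequences over A/C/G/T partitioned into
alternating conserved/variable blocks (conserved ~60% of the length);
relatives are derived by per-block substitution at a low conserved rate and
a high variable rate. Default gene lengths follow the mosquito genes this
tooling targets: 3,900 nt for the large subunit (28S) and 1,900 nt for the
small subunit (18S). Specimen read sets mix host reads with contaminants
(vertebrate blood meal, water-mite parasite, microbiota) as 150 nt
single-end reads with substitution errors; every read carries its true
origin so filter precision/recall can be computed exactly.

All generators are pure functions of (parameters, seed). Indel errors and
quality-ramped Illumina error profiles are not modelled (a documented
limitation that keeps alignment oracles exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import revcomp
from .coi_barcode import FORWARD_ANCHOR, HCO2198, LCO1490, REVERSE_ANCHOR
from .coi_barcode import SangerRead
from .reference_library import ReferenceSequence

_BASES = np.array(list("ACGT"))

LSU_LENGTH = 3_900
SSU_LENGTH = 1_900
DEFAULT_READ_LENGTH = 150
DEFAULT_CONSERVED_DIVERGENCE = 0.02
DEFAULT_VARIABLE_DIVERGENCE = 0.25


@dataclass(frozen=True)
class RrnaArchitecture:
    """Block structure of a synthetic rRNA gene."""

    gene: str                                   # "SSU" | "LSU"
    total_length: int
    blocks: tuple[tuple[str, int], ...]         # (kind, length), kinds conserved|variable
    conserved_divergence: float = DEFAULT_CONSERVED_DIVERGENCE
    variable_divergence: float = DEFAULT_VARIABLE_DIVERGENCE

    def __post_init__(self):
        if sum(l for _, l in self.blocks) != self.total_length:
            raise ValueError("block lengths must sum to total_length")
        if not (0 <= self.conserved_divergence < self.variable_divergence <= 1):
            raise ValueError("need 0 <= conserved_divergence < variable_divergence <= 1")

    def block_spans(self) -> list[tuple[str, int, int]]:
        spans, pos = [], 0
        for kind, length in self.blocks:
            spans.append((kind, pos, pos + length))
            pos += length
        return spans

    def variable_mask(self) -> np.ndarray:
        mask = np.zeros(self.total_length, dtype=bool)
        for kind, s, e in self.block_spans():
            if kind == "variable":
                mask[s:e] = True
        return mask


def default_architecture(
    gene: str = "LSU",
    total_length: Optional[int] = None,
    conserved_divergence: float = DEFAULT_CONSERVED_DIVERGENCE,
    variable_divergence: float = DEFAULT_VARIABLE_DIVERGENCE,
) -> RrnaArchitecture:
    """Alternating conserved/variable blocks, conserved ~60% of the length
    (repeating 300 nt conserved / 200 nt variable units)."""
    if total_length is None:
        total_length = LSU_LENGTH if gene == "LSU" else SSU_LENGTH
    blocks: list[tuple[str, int]] = []
    remaining = total_length
    while remaining > 0:
        for kind, size in (("conserved", 300), ("variable", 200)):
            take = min(size, remaining)
            if take:
                blocks.append((kind, take))
                remaining -= take
    return RrnaArchitecture(gene, total_length, tuple(blocks),
                            conserved_divergence, variable_divergence)


def make_reference(
    architecture: RrnaArchitecture,
    seed: int,
    ref_id: str = "ref",
    taxonomy: Sequence[str] = ("Eukaryota",),
) -> ReferenceSequence:
    """Uniform-random base reference of the architecture's length."""
    rng = np.random.default_rng(seed)
    seq = "".join(_BASES[rng.integers(0, 4, architecture.total_length)])
    return ReferenceSequence(ref_id, seq, tuple(taxonomy))


def derive_relative(
    base: ReferenceSequence,
    architecture: RrnaArchitecture,
    taxonomy: Sequence[str],
    seed: int,
    ref_id: Optional[str] = None,
    conserved_divergence: Optional[float] = None,
    variable_divergence: Optional[float] = None,
) -> ReferenceSequence:
    """Derive a related taxon: substitutions at the conserved rate inside
    conserved blocks and the variable rate inside variable blocks."""
    if len(base.sequence) != architecture.total_length:
        raise ValueError("base length does not match architecture")
    cd = architecture.conserved_divergence if conserved_divergence is None else conserved_divergence
    vd = architecture.variable_divergence if variable_divergence is None else variable_divergence
    rng = np.random.default_rng(seed)
    seq = np.array(list(base.sequence))
    for kind, s, e in architecture.block_spans():
        rate = cd if kind == "conserved" else vd
        if rate <= 0:
            continue
        hit = np.where(rng.random(e - s) < rate)[0] + s
        for pos in hit:
            choices = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = choices[rng.integers(0, 3)]
    return ReferenceSequence(ref_id or f"{base.id}_rel", "".join(seq), tuple(taxonomy))


@dataclass(frozen=True)
class SpecimenMix:
    """Composition of a simulated total-RNA specimen."""

    host_fraction: float
    contaminants: tuple[tuple[str, str, float], ...] = ()   # (label, ref_id, fraction)
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = 0.0
    n_reads: int = 1000
    seed: int = 0

    def __post_init__(self):
        total = self.host_fraction + sum(f for _, _, f in self.contaminants)
        if not np.isclose(total, 1.0):
            raise ValueError(f"fractions must sum to 1 (got {total})")
        if not 0 < self.host_fraction <= 1:
            raise ValueError("host_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    origin: str          # "host" or a contaminant label
    ref_id: str
    start: int
    strand: str          # "+" | "-"


def simulate_specimen(
    mix: SpecimenMix,
    references: dict[str, ReferenceSequence],
    host_ref_ids: Sequence[str],
) -> list[SimulatedRead]:
    """Draw reads from the mixture: per-read categorical origin, uniform
    window on a uniformly chosen origin reference, either strand,
    substitution errors at ``error_rate``. Deterministic under the mix seed.
    """
    rng = np.random.default_rng(mix.seed)
    sources = [("host", tuple(host_ref_ids), mix.host_fraction)]
    sources += [(label, (rid,), frac) for label, rid, frac in mix.contaminants]
    for _, rids, _ in sources:
        for rid in rids:
            if rid not in references:
                raise ValueError(f"reference {rid!r} not provided")
            if len(references[rid].sequence) < mix.read_length:
                raise ValueError(f"reference {rid!r} shorter than the read length")
    probs = np.array([f for _, _, f in sources])
    probs = probs / probs.sum()
    reads: list[SimulatedRead] = []
    for i in range(mix.n_reads):
        src = int(rng.choice(len(sources), p=probs))
        label, rids, _ = sources[src]
        rid = rids[int(rng.integers(0, len(rids)))]
        ref = references[rid].sequence
        start = int(rng.integers(0, len(ref) - mix.read_length + 1))
        window = ref[start: start + mix.read_length]
        if mix.error_rate > 0:
            arr = np.array(list(window))
            for pos in np.where(rng.random(len(arr)) < mix.error_rate)[0]:
                choices = [b for b in "ACGT" if b != arr[pos]]
                arr[pos] = choices[rng.integers(0, 3)]
            window = "".join(arr)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            window = revcomp(window)
        reads.append(SimulatedRead(f"read_{i:06d}", window, label, rid, start, strand))
    return reads


def read_overlaps_variable_block(
    read: SimulatedRead, architecture: RrnaArchitecture
) -> bool:
    """True when the read's source window touches any variable block —
    reads wholly inside conserved blocks are inherently ambiguous between
    taxa and are exempt from classifier recall requirements."""
    mask = architecture.variable_mask()
    return bool(mask[read.start: read.start + len(read.sequence)].any())


# --------------------------------------------------------------------------
# COI amplicon read pairs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoiPairSim:
    source: str
    forward: SangerRead
    reverse: SangerRead
    interior_start: int        # first base after the forward anchor trim
    interior_end: int          # first base of the planted reverse-anchor site

    @property
    def interior(self) -> str:
        """The anchor-to-anchor span the trimmed consensus reproduces.

        With both Folmer primers inside a 658 nt product the anchor-bounded
        interior is 607 nt — shorter than the 621 nt configured consensus
        length, so the consensus of an error-free pair equals this span and
        is flagged as not reaching the configured length.
        """
        return self.source[self.interior_start: self.interior_end]


def simulate_coi_pair(
    seed: int,
    source_length: int = 658,
    read_span: int = 420,
    error_rate: float = 0.0,
    tail_len: int = 0,
    base_quality: int = 40,
    tail_quality: int = 20,
) -> CoiPairSim:
    """Simulate a Folmer COI amplicon and its Sanger read pair.

    The source begins with the forward primer (LCO1490) and ends with the
    reverse complement of the reverse primer (HCO2198). The forward trim
    anchor TTTTGG is planted immediately after the forward primer; a
    GGNTCT-matching site is planted so the reverse read carries its anchor
    immediately after the primer, exercising both trimming rules. The
    forward read covers the 5' span [0, read_span), the reverse read the
    reverse complement of the 3' span; the spans must overlap. Optional
    low-quality tails (below Q30) are appended to both reads to exercise
    quality trimming.
    """
    if read_span <= source_length / 2:
        raise ValueError("read_span must exceed half the source length so the reads overlap")
    if read_span > source_length:
        raise ValueError("read_span cannot exceed the source length")
    rng = np.random.default_rng(seed)
    rev_anchor_site = revcomp(REVERSE_ANCHOR.replace("N", "A"))   # appears as GGATCT in the read
    n_random = source_length - len(LCO1490) - len(FORWARD_ANCHOR) - 6 - len(HCO2198)
    middle = "".join(_BASES[rng.integers(0, 4, n_random)])
    source = LCO1490 + FORWARD_ANCHOR + middle + rev_anchor_site + revcomp(HCO2198)
    assert len(source) == source_length
    interior_start = len(LCO1490)
    # the reverse trim stops at the planted anchor site, which stays in the
    # consensus: the interior runs from the forward anchor to the reverse primer
    interior_end = source_length - len(HCO2198)

    def with_errors(seq: str) -> str:
        if error_rate <= 0:
            return seq
        arr = np.array(list(seq))
        for pos in np.where(rng.random(len(arr)) < error_rate)[0]:
            choices = [b for b in "ACGT" if b != arr[pos]]
            arr[pos] = choices[rng.integers(0, 3)]
        return "".join(arr)

    fwd_seq = with_errors(source[:read_span])
    rev_seq = with_errors(revcomp(source[-read_span:]))
    tail = lambda: "".join(_BASES[rng.integers(0, 4, tail_len)])
    fq = [base_quality] * len(fwd_seq)
    rq = [base_quality] * len(rev_seq)
    if tail_len:
        fwd_seq, rev_seq = fwd_seq + tail(), rev_seq + tail()
        fq += [tail_quality] * tail_len
        rq += [tail_quality] * tail_len
    return CoiPairSim(
        source=source,
        forward=SangerRead("forward", fwd_seq, tuple(fq)),
        reverse=SangerRead("reverse", rev_seq, tuple(rq)),
        interior_start=interior_start,
        interior_end=interior_end,
    )
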