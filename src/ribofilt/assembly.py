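"""Assembly of filtered reads into full-length rRNA consensus sequences.

Four routes are provided:

* ``greedy_assemble`` — a deterministic internal overlap-layout assembler
  (longest exact suffix-prefix overlap first, both strands) for desk-scale
  work and tests;
* ``polish_contigs`` — majority-vote consensus polish that re-maps reads
  onto assembled contigs, correcting the residual per-read errors that
  exact-overlap merging cannot;
* ``guided_consensus`` — reference-guided assembly mirroring the
  trusted-contig rescue used for specimens whose reads resist de novo
  assembly: reads are placed on a close relative's sequence and a per-column
  majority vote yields the consensus;
* ``external_assembler_adapter`` — a contract for driving an external
  assembler (SPAdes-style CLI: kmer list, rna mode, trusted contigs) and
  parsing its contigs.

``bin_contigs`` separates host from co-assembled foreign (e.g. water-mite
parasite) contigs by identity to a host reference, annotating the bins with
their relative coverage.
"""

from __future__ import annotations

import heapq
import itertools
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from . import _align
from ._seq import encode, percent_identity, revcomp
from .reference_library import ReferenceSequence


@dataclass
class Contig:
    """An assembled sequence with per-base coverage and provenance."""

    id: str
    sequence: str
    per_base_coverage: np.ndarray
    mode: str = "de_novo"              # "de_novo" | "guided"
    guide_id: Optional[str] = None
    low_depth_positions: tuple[int, ...] = ()

    def __post_init__(self):
        self.per_base_coverage = np.asarray(self.per_base_coverage, dtype=float)
        if len(self.per_base_coverage) != len(self.sequence):
            raise ValueError(f"contig {self.id}: coverage length != sequence length")

    @property
    def mean_coverage(self) -> float:
        return float(self.per_base_coverage.mean())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblerSpec:
    """Parameters handed to an external assembler."""

    kmer_lengths: tuple[int, ...] = (31, 51, 71)
    mode_flags: tuple[str, ...] = ("--rna",)
    trusted_contigs: Optional[tuple[ReferenceSequence, ...]] = None

    def __post_init__(self):
        ks = self.kmer_lengths
        if any(k % 2 == 0 for k in ks) or list(ks) != sorted(ks):
            raise ValueError("kmer lengths must be odd and ascending")


# --------------------------------------------------------------------------
# k-mer spectrum read correction
# --------------------------------------------------------------------------

def correct_reads(
    reads: Sequence[str],
    k: int = 25,
    min_count: int = 3,
    max_rounds: int = 3,
) -> list[str]:
    """Correct isolated substitution errors by the k-mer spectrum.

    Exact-overlap assembly requires error-free overlap regions, so isolated
    sequencing errors fragment contigs; a k-mer whose (canonical) count
    falls below ``min_count`` is treated as error-containing, and the
    substitution that turns a run of weak k-mers solid is applied. Reads
    whose weak stretches cannot be resolved (clustered errors, genuinely
    rare sequence) are left untouched — a wrong correction is worse than a
    fragmented contig.
    """
    from collections import Counter

    counts: Counter = Counter()
    for r in reads:
        for i in range(len(r) - k + 1):
            km = r[i: i + k]
            rc = revcomp(km)
            counts[km if km <= rc else rc] += 1

    def weak_indices(seq: str) -> list[int]:
        out = []
        for i in range(len(seq) - k + 1):
            km = seq[i: i + k]
            rc = revcomp(km)
            if counts[km if km <= rc else rc] < min_count:
                out.append(i)
        return out

    def runs(indices: list[int]) -> list[tuple[int, int]]:
        out, start = [], indices[0]
        prev = start
        for i in indices[1:]:
            if i != prev + 1:
                out.append((start, prev))
                start = i
            prev = i
        out.append((start, prev))
        return out

    corrected = []
    for r in reads:
        seq = r
        for _round in range(max_rounds):
            weak = weak_indices(seq)
            if not weak:
                break
            n_weak_before = len(weak)
            changed = False
            for a, b in runs(weak):
                # an error at position p makes k-mers [p-k+1, p] weak, so
                # the culprit sits in [a, b + k - 1]
                lo, hi = a, min(b + k - 1, len(seq) - 1)
                best = None
                weak_set = set(weak)
                for p in range(lo, hi + 1):
                    window = range(max(0, p - k + 1), min(p, len(seq) - k) + 1)
                    before = sum(1 for i in window if i in weak_set)
                    orig = seq[p]
                    for base in "ACGT":
                        if base == orig:
                            continue
                        trial = seq[:p] + base + seq[p + 1:]
                        after = 0
                        for i in window:
                            km = trial[i: i + k]
                            rc = revcomp(km)
                            if counts[km if km <= rc else rc] < min_count:
                                after += 1
                        n_weak = n_weak_before - before + after
                        if n_weak < n_weak_before and (best is None or n_weak < best[0]):
                            best = (n_weak, p, base)
                if best is not None:
                    _n, p, base = best
                    seq = seq[:p] + base + seq[p + 1:]
                    changed = True
                    break      # re-derive runs after each applied fix
            if not changed:
                break
        corrected.append(seq)
    return corrected


# --------------------------------------------------------------------------
# greedy overlap-layout assembly
# --------------------------------------------------------------------------

class _Work:
    __slots__ = ("seq", "placements")

    def __init__(self, seq: str, placements: list[tuple[int, int, bool]]):
        self.seq = seq
        # placements: (read_index, offset on this contig, reverse-complemented?)
        self.placements = placements

    def oriented(self, rc: bool) -> str:
        return revcomp(self.seq) if rc else self.seq

    def flipped_placements(self, read_lengths: Sequence[int]) -> list[tuple[int, int, bool]]:
        L = len(self.seq)
        return [
            (ridx, L - off - read_lengths[ridx], not rc)
            for ridx, off, rc in self.placements
        ]


def _longest_overlap(x: str, y: str, k: int) -> int:
    """Longest o >= k with x[-o:] == y[:o] (and o <= len(y)); 0 if none."""
    seed = y[:k]
    start = max(0, len(x) - len(y))
    p = x.find(seed, start)
    while p != -1:
        o = len(x) - p
        if o >= k and x[p:] == y[:o]:
            return o
        p = x.find(seed, p + 1)
    return 0


def greedy_assemble(reads: Sequence[str], min_overlap: int) -> list[Contig]:
    """Merge reads by longest exact suffix-prefix overlap until none remains.

    Both strands are considered. Ties in overlap length are broken toward
    the lexicographically smaller merged sequence (a merged sequence and its
    reverse complement are the same assembly, so this also canonicalises
    strand choice). Unmergeable reads become singleton contigs. Per-base
    coverage counts the reads covering each contig position.
    """
    if not reads:
        raise ValueError("no reads to assemble")
    if min_overlap >= min(len(r) for r in reads):
        raise ValueError("min_overlap must be smaller than the read length")
    k = min_overlap
    read_lengths = [len(r) for r in reads]
    contigs: dict[int, _Work] = {
        i: _Work(seq.upper(), [(i, 0, False)]) for i, seq in enumerate(reads)
    }
    alive = set(contigs)
    next_id = len(reads)
    heap: list[tuple[int, int, bool, int, bool]] = []

    def push_candidates(a: int, others: Iterable[int]) -> None:
        wa = contigs[a]
        for b in others:
            if b == a:
                continue
            wb = contigs[b]
            for a_rc, b_rc in itertools.product((False, True), repeat=2):
                o = _longest_overlap(wa.oriented(a_rc), wb.oriented(b_rc), k)
                if o:
                    heapq.heappush(heap, (-o, a, a_rc, b, b_rc))
                o = _longest_overlap(wb.oriented(b_rc), wa.oriented(a_rc), k)
                if o:
                    heapq.heappush(heap, (-o, b, b_rc, a, a_rc))

    ids = sorted(alive)
    for idx, a in enumerate(ids):
        push_candidates(a, ids[idx + 1:])

    def merged_seq(entry) -> str:
        _, a, a_rc, b, b_rc = entry
        xa, xb = contigs[a].oriented(a_rc), contigs[b].oriented(b_rc)
        o = _longest_overlap(xa, xb, k)
        return xa + xb[o:]

    while heap:
        top = heapq.heappop(heap)
        neg_o, a, a_rc, b, b_rc = top
        if a not in alive or b not in alive:
            continue
        # gather equal-overlap candidates for the lexicographic tie-break
        ties = [top]
        stash = []
        while heap and heap[0][0] == neg_o:
            e = heapq.heappop(heap)
            if e[1] in alive and e[3] in alive:
                ties.append(e)
            # invalid entries are dropped
        if len(ties) > 1:
            ties.sort(key=lambda e: (merged_seq(e), e[1:]))
            stash = ties[1:]
        chosen = ties[0]
        for e in stash:
            heapq.heappush(heap, e)

        _, a, a_rc, b, b_rc = chosen
        wa, wb = contigs[a], contigs[b]
        xa, xb = wa.oriented(a_rc), wb.oriented(b_rc)
        o = _longest_overlap(xa, xb, k)
        pa = wa.flipped_placements(read_lengths) if a_rc else list(wa.placements)
        pb = wb.flipped_placements(read_lengths) if b_rc else list(wb.placements)
        shift = len(xa) - o
        merged = _Work(xa + xb[o:], pa + [(r, off + shift, rc) for r, off, rc in pb])
        alive.discard(a)
        alive.discard(b)
        del contigs[a], contigs[b]
        cid = next_id
        next_id += 1
        contigs[cid] = merged
        push_candidates(cid, list(alive))
        alive.add(cid)

    out = []
    works = sorted(
        (contigs[c] for c in alive), key=lambda w: (-len(w.seq), min(w.seq, revcomp(w.seq)))
    )
    for i, w in enumerate(works):
        cov = np.zeros(len(w.seq))
        for ridx, off, _rc in w.placements:
            cov[off: off + read_lengths[ridx]] += 1
        out.append(Contig(f"contig_{i + 1}", w.seq, cov, mode="de_novo"))
    return out


# --------------------------------------------------------------------------
# consensus by read pileup (polish + guided assembly)
# --------------------------------------------------------------------------

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_IDX_BASE = "ACGT"


def _place_reads(
    template: str,
    reads: Sequence[str],
    match: int,
    mismatch: int,
    min_placement_frac: float,
    allow_overhang: bool = False,
    min_overlap: int = 50,
) -> list[tuple[int, int, str]]:
    """Best ungapped placement (either strand) of each read on the template.

    With ``allow_overhang`` a read may extend past either template end by up
    to ``len(read) - min_overlap`` (offsets can be negative); otherwise the
    read must fit entirely inside the template. A placement is accepted when
    its score reaches ``min_placement_frac * match * overlap_length``.
    Returns (read_index, offset, oriented_sequence) tuples; ties between
    strands go to the forward strand, between offsets to the smaller one.
    """
    t = encode(template)
    L = len(template)
    placements = []
    for i, read in enumerate(reads):
        if not allow_overhang and len(read) > L:
            continue
        if allow_overhang and min(len(read), L) < min_overlap:
            continue
        best_score, best_off, best_seq = None, 0, read
        for seq in (read, revcomp(read)):
            if allow_overhang:
                s, off = _align.best_overlap_placement(
                    encode(seq), t, match, mismatch, min(min_overlap, len(seq), L))
            else:
                s, off = _align.best_ungapped_placement(encode(seq), t, match, mismatch)
            if best_score is None or s > best_score:
                best_score, best_off, best_seq = s, off, seq
        overlap = min(best_off + len(best_seq), L) - max(best_off, 0)
        if best_score >= min_placement_frac * match * overlap:
            placements.append((i, best_off, best_seq))
    return placements


def _vote(
    template: str,
    placements: Sequence[tuple[int, int, str]],
    min_depth: int,
) -> tuple[str, np.ndarray, tuple[int, ...]]:
    L = len(template)
    counts = np.zeros((4, L), dtype=np.int64)
    depth = np.zeros(L, dtype=np.int64)
    for _i, off, seq in placements:
        for j, b in enumerate(seq):
            col = off + j
            if not 0 <= col < L:
                continue
            idx = _BASE_IDX.get(b)
            if idx is not None:
                counts[idx, col] += 1
                depth[col] += 1
    bases = []
    low_depth = []
    for j in range(L):
        if depth[j] < min_depth:
            bases.append(template[j])
            low_depth.append(j)
            continue
        col = counts[:, j]
        top = col.max()
        winners = [i for i in range(4) if col[i] == top]
        tmpl_idx = _BASE_IDX.get(template[j])
        if tmpl_idx in winners:   # ties resolve toward the template
            bases.append(template[j])
        else:
            bases.append(_IDX_BASE[winners[0]])
    return "".join(bases), depth, tuple(low_depth)


def guided_consensus(
    reads: Sequence[str],
    guide: ReferenceSequence,
    min_depth: int = 2,
    match: int = 2,
    mismatch: int = -3,
    min_placement_frac: float = 0.7,
) -> Contig:
    """Reference-guided consensus: reads placed on the guide, per-column
    majority vote; columns below ``min_depth`` fall back to the guide base
    and are flagged in ``low_depth_positions``.

    The placement threshold keeps unrelated reads (e.g. a co-occurring
    parasite's rRNA) off the guide so the consensus reflects the target
    organism only. With the default score fraction 0.7 (match +2 /
    mismatch -3) a read must be roughly 88% identical to its guide placement
    to be used.
    """
    if not reads:
        raise ValueError("no reads for guided consensus")
    if max(len(r) for r in reads) > len(guide.sequence):
        raise ValueError("guide must be at least as long as the reads")
    _align.warmup()
    placements = _place_reads(guide.sequence, reads, match, mismatch, min_placement_frac)
    if not placements:
        raise ValueError("guide unrelated to read set: no read could be placed")
    seq, depth, low = _vote(guide.sequence, placements, min_depth)
    return Contig(
        f"guided_{guide.id}", seq, depth.astype(float), mode="guided",
        guide_id=guide.id, low_depth_positions=low,
    )


def assign_reads_competitively(
    reads: Sequence[str],
    templates: Sequence[str],
    match: int = 2,
    mismatch: int = -3,
    min_placement_frac: float = 0.7,
) -> list[list[str]]:
    """Assign each read to the template it matches best.

    Co-occurring organisms (host and parasite) share near-identical
    conserved rRNA blocks, so an absolute identity cut cannot decide where
    a conserved-block read belongs; comparing the read against both
    candidate templates can — each read goes to the template with the
    higher placement score (ties to the earlier template; reads below the
    placement threshold on every template are dropped). This is the
    read-partitioning effect a trusted-contig co-assembly achieves.
    """
    if not templates:
        raise ValueError("no templates")
    _align.warmup()
    enc = [encode(t) for t in templates]
    bins: list[list[str]] = [[] for _ in templates]
    for read in reads:
        best_i, best_s = None, None
        for i, t in enumerate(enc):
            if len(read) > len(t):
                continue
            for seq in (read, revcomp(read)):
                s, _off = _align.best_ungapped_placement(encode(seq), t, match, mismatch)
                if best_s is None or s > best_s:
                    best_i, best_s = i, s
        if best_i is not None and best_s >= min_placement_frac * len(read) * match:
            bins[best_i].append(read)
    return bins


def polish_contigs(
    contigs: Sequence[Contig],
    reads: Sequence[str],
    match: int = 2,
    mismatch: int = -3,
    min_placement_frac: float = 0.9,
    min_contig_length: int = 0,
) -> list[Contig]:
    """Majority-vote polish: re-map all reads onto each contig and vote.

    Exact-overlap assembly leaves every contig column the verbatim copy of a
    single read, so sequencing errors survive at the per-read error rate;
    the vote over the full pileup removes them. Contigs shorter than
    ``min_contig_length`` are passed through unchanged. The stringent
    default placement fraction (0.9 ~= 96% identity) keeps reads from
    merely-homologous sequences out of the pileup.
    """
    _align.warmup()
    out = []
    for c in contigs:
        if len(c) < max(min_contig_length, 1):
            out.append(c)
            continue
        placements = _place_reads(c.sequence, reads, match, mismatch,
                                  min_placement_frac, allow_overhang=True)
        if not placements:
            out.append(c)
            continue
        seq, depth, low = _vote(c.sequence, placements, min_depth=1)
        out.append(
            Contig(c.id, seq, np.maximum(depth, 1).astype(float), mode=c.mode,
                   guide_id=c.guide_id, low_depth_positions=low)
        )
    return out


def assemble_reads(
    reads: Sequence[str],
    min_overlap: int = 40,
    correct: bool = True,
    polish: bool = True,
    rounds: int = 2,
    min_polish_length: int = 300,
) -> list[Contig]:
    """The internal assembly pipeline: k-mer read correction, greedy
    overlap-layout assembly, majority-vote polish, and a second greedy
    round over the polished contigs.

    Exact-overlap chains stall where residual read errors sit at contig
    tips; polishing restores consensus bases there (overhanging read
    placements give the tips real pileup depth), after which a further
    greedy round joins the chains. Final per-base coverage comes from the
    last polish pileup.
    """
    working = correct_reads(reads) if correct else list(reads)
    contigs = greedy_assemble(working, min_overlap)
    if not polish:
        return contigs
    contigs = polish_contigs(contigs, working, min_contig_length=min_polish_length)
    for _ in range(rounds - 1):
        merged = greedy_assemble([c.sequence for c in contigs], min_overlap)
        if len(merged) == len(contigs):
            contigs = merged
            break
        contigs = merged
    contigs = polish_contigs(contigs, working, min_contig_length=min_polish_length)
    return contigs


# --------------------------------------------------------------------------
# contig binning (host vs foreign)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BinResult:
    host_bin: tuple[Contig, ...]
    foreign_bin: tuple[Contig, ...]
    host_mean_coverage: Optional[float]
    foreign_mean_coverage: Optional[float]
    coverage_ratio_foreign_to_host: Optional[float]
    identities: dict[str, float] = field(default_factory=dict)


def bin_contigs(
    contigs: Sequence[Contig],
    host_reference: ReferenceSequence,
    identity_fn: Callable[[str, str], float] | None = None,
    host_identity_min: float = 97.0,
) -> BinResult:
    """Split contigs into host vs foreign by identity to a host reference.

    Contigs at >= ``host_identity_min`` percent identity to the host
    reference go to the host bin. The 97% default sits above the ~95%
    identity a merely related non-host sequence shows while tolerating
    intraspecific variation. Each bin is annotated with its length-weighted
    mean coverage and the foreign/host coverage ratio.
    """
    if not contigs:
        raise ValueError("no contigs to bin")
    ident = identity_fn or (lambda c, h: percent_identity(c, h))
    host, foreign, idents = [], [], {}
    for c in contigs:
        pid = ident(c.sequence, host_reference.sequence)
        idents[c.id] = pid
        (host if pid >= host_identity_min else foreign).append(c)

    def wmean(bin_):
        if not bin_:
            return None
        return sum(c.mean_coverage * len(c) for c in bin_) / sum(len(c) for c in bin_)

    h_cov, f_cov = wmean(host), wmean(foreign)
    ratio = (f_cov / h_cov) if (h_cov and f_cov) else None
    return BinResult(tuple(host), tuple(foreign), h_cov, f_cov, ratio, idents)


# --------------------------------------------------------------------------
# FASTA round trip + external assembler adapter
# --------------------------------------------------------------------------

_COV_RE = re.compile(r"length_(\d+)_cov_([\d.eE+-]+)")


def write_contigs_fasta(contigs: Sequence[Contig], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(
                f">{c.id}_length_{len(c)}_cov_{c.mean_coverage:.6g} mode={c.mode}\n"
                f"{c.sequence}\n"
            )


def parse_contigs_fasta(path: str | Path, reads: Sequence[str] | None = None) -> list[Contig]:
    """Parse assembler FASTA output; coverage from SPAdes-style
    ``..._length_L_cov_C`` headers when present, else by read re-mapping
    (or 1.0 if no reads are supplied)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        m = _COV_RE.search(rec.description)
        name = rec.id
        if m:
            cov = float(m.group(2))
            name = re.sub(r"_length_\d+_cov_[\d.eE+-]+$", "", rec.id)
        elif reads:
            placements = _place_reads(seq, [r for r in reads if len(r) <= len(seq)],
                                      2, -3, 0.9)
            depth = np.zeros(len(seq))
            for _i, off, s in placements:
                depth[off: off + len(s)] += 1
            cov = float(depth.mean()) if len(depth) else 1.0
        else:
            cov = 1.0
        out.append(Contig(name, seq, np.full(len(seq), cov)))
    return out


def external_assembler_adapter(
    kept_reads_path: str | Path,
    spec: AssemblerSpec = AssemblerSpec(),
    binary: str = "spades.py",
    outdir: str | Path | None = None,
) -> list[Contig]:
    """Run an external (SPAdes-style) assembler on the kept reads.

    The binary is probed first; when absent a clear error points to the
    internal ``greedy_assemble``/``polish_contigs`` fallback. A non-zero
    exit surfaces the captured log.
    """
    exe = shutil.which(binary)
    if exe is None:
        raise FileNotFoundError(
            f"external assembler {binary!r} not found on PATH; "
            "use the internal assembler (greedy_assemble + polish_contigs) instead"
        )
    outdir = Path(outdir) if outdir else Path(kept_reads_path).parent / "assembly_out"
    outdir.mkdir(parents=True, exist_ok=True)
    cmd = [exe, *spec.mode_flags, "-s", str(kept_reads_path),
           "-k", ",".join(map(str, spec.kmer_lengths)), "-o", str(outdir)]
    if spec.trusted_contigs:
        trusted = outdir / "trusted_contigs.fasta"
        with open(trusted, "w") as fh:
            for r in spec.trusted_contigs:
                fh.write(f">{r.id}\n{r.sequence}\n")
        cmd += ["--trusted-contigs", str(trusted)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"{binary} exited with {proc.returncode}\n--- captured log ---\n"
            f"{proc.stdout}\n{proc.stderr}"
        )
    contigs_fa = outdir / "contigs.fasta"
    if not contigs_fa.exists():
        raise RuntimeError(f"{binary} produced no contigs.fasta under {outdir}")
    return parse_contigs_fasta(contigs_fa)
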