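# Methods

## The classification model

Every read is aligned (both strands) against two disjoint reference sets cut
from a taxonomy-annotated rRNA database at an anchor node, by default
`Insecta`. Membership is decided by exact equality of the anchor against
individual taxonomy ranks, never substring search, so a rank such as
"Insectarium" cannot leak into the insect side. The read's statistic is the
ratio of its best raw local-alignment scores, Insecta over Non-Insecta.
Four categories follow: Insecta-only hits, ratio ≥ 1, ratio < 1, and no
Insecta hit. A read enters assembly when it is Insecta-only or its ratio
reaches the threshold (0.8, inclusive). The inclusive comparison is the
default because the only checkable published counts are stated against a
"≥ 0.8" cut; a strict variant is kept behind `FilterConfig(inclusive=False)`.
The 0.8 threshold is deliberately conservative: with non-exhaustive
libraries the goal is to remove only reads clearly of non-insect origin.
Reads falling entirely inside conserved blocks are inherently ambiguous —
their ratio sits near 1 regardless of origin — and the method does not
claim to classify them; its value lies in removing variable-block
contaminant reads, which are the ones that derail assembly.

## Scoring

The internal scorer is an exact affine-gap Smith–Waterman dynamic program
(numba-compiled), not a seeded heuristic. Scores are integers; a gap of
length k costs `gap_open + k·gap_extend`. Defaults follow the blastn task:
match +2, mismatch −3, gap open −5, gap extend −2. Ratios are invariant
under common positive scaling of all parameters, so the absolute scale is
immaterial. "Hit" existence is a raw-score floor (`min_report_score`,
default 50) rather than an E-value: E-values are meaningless against the
desk-scale synthetic libraries used here. The external path
(`parse_external_hits`, BLAST outfmt 6) instead inherits the aligner's own
reporting threshold — the two paths are deliberately documented as
non-identical; whichever score column (bitscore, or a raw `score` column 13)
is chosen must be used for both libraries. N never matches, including N vs
N.

## Assembly

The internal assembler is three deliberate stages:

1. **k-mer spectrum correction** (`correct_reads`, k = 25, solid count ≥ 3).
   Exact-overlap merging requires error-free overlaps; at a 1% substitution
   rate each chain junction — whose overlap length is fixed by read
   geometry — fails with appreciable probability and contigs fragment. A
   substitution that turns a run of weak k-mers solid is accepted;
   unresolvable reads are left untouched, since a wrong correction is worse
   than a short contig.
2. **Greedy overlap-layout** (`greedy_assemble`): repeatedly merge the pair
   of contigs with the longest exact suffix–prefix overlap (≥ `min_overlap`,
   default 40; both strands), ties broken toward the lexicographically
   smaller merged sequence, which also canonicalises strand choice. The
   procedure is deterministic and input-order independent.
3. **Majority-vote polish and a second greedy round** (`polish_contigs`,
   `assemble_reads`): all reads are re-placed on each contig — placements
   may overhang contig ends, so terminal columns receive real pileup
   depth — and each column takes the majority base (ties keep the existing
   base). Polished tips are consensus-accurate, so one further greedy round
   joins chains whose junctions had been blocked by residual errors. Final
   per-base coverage is the last polish pileup.

The greedy core keeps the exact-overlap contract; correction and polish are
the package's own additions that make the exact-overlap design hold up at
realistic error rates.

`guided_consensus` mirrors the trusted-contig rescue for specimens whose
reads resist de novo assembly: reads are placed at their best ungapped
position on a close relative's sequence, each column takes the majority
base, ties resolve to the guide (conservative toward the trusted sequence),
and columns under `min_depth` (default 2) fall back to the guide base and
are flagged in `low_depth_positions`. A placement threshold
(`min_placement_frac`, default 0.7 ≈ 88% identity at +2/−3) keeps unrelated
reads off the guide. Placement is ungapped — adequate because the simulator
is substitution-only and guides are close relatives; indel-divergent guides
are out of scope for v1.

When a specimen carries a second organism at higher depth (the water-mite
scenario), no absolute identity threshold separates conserved-block reads
of the two; `assign_reads_competitively` instead gives each read to
whichever template it matches best — first the dominant organism's
consensus is built on its own related reference, then reads are split
between that consensus and the host guide. This is the read-partitioning
effect a trusted-contig co-assembly achieves.

`bin_contigs` separates host from foreign contigs at 97% identity to a host
reference (edlib infix alignment; identity = matches over alignment columns,
end gaps excluded). The 97% default sits above the ~95% a merely related
non-host sequence shows while tolerating intraspecific variation, and each
bin is annotated with its length-weighted mean coverage and the
foreign/host coverage ratio. The external-assembler adapter
(`external_assembler_adapter`) probes for a SPAdes-style binary, passes
k-mer list / rna-mode / trusted-contigs flags, and parses
`NODE_i_length_L_cov_C` headers; when the binary is absent it points to the
internal fallback rather than failing silently.

## Probe tiling

Depletion probes are non-overlapping antisense windows (80 nt default) over
each target. When the target length is not a multiple of the probe length,
the default `right_anchor` policy adds a final window flush with the 3' end
(overlapping its predecessor) so coverage is total — full coverage of the
variable 3' end matters for depletion — while `drop` discards the
remainder. The order-sheet manifest carries the pool concentration
(0.04 µM default) and flags duplicate probe sequences, which arise when
targets share exact conserved blocks.

## COI barcoding

Sanger pairs are end-trimmed of bases below Q30, then 5'-anchored at the
first occurrence of TTTTGG (forward) or GGNTCT (reverse, N matching any
base); trimming is idempotent. The consensus takes the best ungapped
overlap of the forward read against the reverse complement of the reverse
read (most matching columns, ties to the longer overlap) and rejects pairs
whose overlap identity falls below 98% as discordant. Disagreements take
the higher-quality base; absent or tied qualities favour the forward read —
a deterministic stand-in for manual trace inspection. The consensus is cut
at 621 nt and extended to at most 699 nt only where both reads cover the
extra span. On the synthetic 658 nt Folmer amplicon, whose product includes
both primers (25 + 26 nt), the anchor-to-anchor interior is 607 nt — the
geometric maximum — so the round-trip consensus is that interior, flagged
as below the configured length.

Species assignment applies ordered rules to a ranked hit list: all hits
below the 95% species threshold but within one genus → genus-only ("Culex
sp."); top two hits of different species within one substitution's worth of
identity (100/621 ≈ 0.16%) with the morphological species among them →
ambiguous, morphology retained; qualifying top hit matching morphology →
confirmed; qualifying top hit beating the morphological species' identity
by more than 2% → revised (when the morphological species has no reference
hit, the margin is taken against the best hit of any other species, the
sister-species comparison used in practice); otherwise ambiguous, and with
no qualifying hit and no reference at all, no-reference. Equal-identity
hits are order-invariant.

## Synthetic data

References are uniform-random A/C/G/T sequences partitioned into
alternating conserved/variable blocks (repeating 300 nt conserved / 200 nt
variable units, conserved ≈ 60% of length; LSU 3,900 nt, SSU 1,900 nt).
Relatives are derived by i.i.d. per-site substitution at a conserved rate
and a variable rate: 2%/25% between genera (the Insecta-library relative),
0.5%/3% for a conspecific guide, 3%/45% for the vertebrate blood source,
4%/50% for the water-mite-like parasite, and a uniform 5% for the mite
database record (so parasite-vs-record identity ≈ 95%). Specimen read sets
draw per-read origins categorically, uniform windows on the origin
reference, either strand, substitution errors at the configured rate;
every read carries its true origin, so filter precision and recall are
computed exactly. The standard contaminated specimen is 70% host / 30%
vertebrate blood, 150 nt reads, 1% error, 1,600 reads (≈30× host depth over
the 5.8 kb of both genes — ample for exact-overlap assembly at desk scale);
the parasitised specimen mixes host at 12× with the parasite at 120×. COI
amplicons are 658 nt, primer-flanked, with the trim anchors planted
immediately after the primers and optional sub-Q30 tails.

What the generator does **not** emulate: indels (substitution-only keeps
alignment oracles exact), quality-ramped Illumina error profiles, copy
number and intragenomic rRNA variation, chimeric reads, and real SILVA
taxonomy breadth. Passing tests therefore demonstrate the algorithmic
behaviour of the method under its stated model of rRNA structure, not
performance on any particular sequencing run.

## Numerical and degenerate-input choices

Ratio ties (ρ = 1) are classed on the kept side; the filter keeps them at
any threshold ≤ 1 anyway. Histogram bins are half-open with a closed last
bin; ratios above the cap land in the last bin; Insecta-only and no-hit
reads occupy separate buckets so bucket counts always sum to the read
count. Empty read sets, empty libraries, anchor-less headers, discordant
COI pairs, guide-unrelated read sets and id collisions during augmentation
are all hard errors rather than silent defaults. Percentages are exact
floats internally; display rounding is two decimals.

## Known limitations

- The greedy assembler is O(n²) in read count and meant for desk-scale
  work; the external-assembler adapter is the route for real libraries.
- Ungapped read placement in polish/guided modes assumes
  substitution-dominated divergence.
- Gene boundaries (28S vs 18S) within de novo contigs are not called; in
  guided mode they follow the guide annotation.
- Iterative augmentation stops at a kept-set fixpoint or the cycle cap;
  no other convergence diagnostics are attempted.
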