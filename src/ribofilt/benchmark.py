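"""Standard synthetic study conditions and their evaluation.

These functions wire the synthetic generator to the filtration/assembly
machinery under the study conditions the package is designed for — a
mosquito specimen contaminated with vertebrate blood-meal rRNA, and a
specimen co-infested by a water-mite parasite whose rRNA swamps the host's
at ~10-fold coverage — and measure how well the true host sequences are
recovered. They are used by the test suite and the reproduction script; all
randomness flows from a single integer seed.

Problem sizes are desk-scale by design: ~30x host read depth over one
3,900 nt large-subunit and one 1,900 nt small-subunit gene, which is ample
for exact-overlap assembly while keeping a full run in minutes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._seq import best_alignment_span, percent_identity
from .assembly import (
    assemble_reads,
    assign_reads_competitively,
    bin_contigs,
    guided_consensus,
)
from .coi_barcode import build_consensus, trim_read
from .probe_design import tile_probes
from .ratio_filter import FilterConfig, filter_reads, summarize
from .read_scoring import ScoredRead, ScoringParams, score_reads
from .reference_library import LibraryPartition, ReferenceSequence, partition_by_node
from .synthetic_data import (
    RrnaArchitecture,
    SimulatedRead,
    SpecimenMix,
    default_architecture,
    derive_relative,
    make_reference,
    read_overlaps_variable_block,
    simulate_coi_pair,
    simulate_specimen,
)

# Fig 2B worked example, specimen "CF S27": the three printed category counts
FIG2B_COUNTS = {"kept": 175_671, "below": 325, "no_insecta": 6_423}


def fig2b_summary():
    """Recompute the ratio-filter summary from the printed read counts of
    the worked example (175,671 kept / 325 below threshold / 6,423 without
    Insecta hits)."""
    scored = (
        [ScoredRead(f"k{i}", 100.0, 100.0) for i in range(FIG2B_COUNTS["kept"])]
        + [ScoredRead(f"b{i}", 50.0, 100.0) for i in range(FIG2B_COUNTS["below"])]
        + [ScoredRead(f"n{i}", None, 100.0) for i in range(FIG2B_COUNTS["no_insecta"])]
    )
    return summarize(scored, FilterConfig(threshold=0.8, inclusive=True))


def study_references(seed: int) -> dict:
    """The reference cast for the contaminated-specimen study conditions.

    * host LSU/SSU genes (the truth to recover),
    * an Insecta-library relative of the host (different genus: 2%
      divergence in conserved blocks, 25% in variable blocks),
    * a conspecific-level guide (0.5% / 3%) for guided rescue and binning,
    * a vertebrate blood-meal source (3% / 45%),
    * a water-mite-like parasite (4% / 50% from the host) and a mite
      reference ~95% identical to it (5% uniform), mirroring a foreign
      contig identified via a related database record.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(12)]
    arch = {"LSU": default_architecture("LSU"), "SSU": default_architecture("SSU")}
    refs: dict[str, ReferenceSequence] = {}
    k = 0
    for gene in ("LSU", "SSU"):
        a = arch[gene]
        host = make_reference(
            a, sub[k], f"host_{gene}",
            ("Eukaryota", "Arthropoda", "Insecta", "Culicidae", "Hostomyia specimen"),
        )
        refs[host.id] = host
        refs[f"insecta_rel_{gene}"] = derive_relative(
            host, a,
            ("Eukaryota", "Arthropoda", "Insecta", "Culicidae", "Relatomyia generica"),
            sub[k + 1], ref_id=f"insecta_rel_{gene}",
        )
        refs[f"guide_{gene}"] = derive_relative(
            host, a,
            ("Eukaryota", "Arthropoda", "Insecta", "Culicidae", "Hostomyia conspecific"),
            sub[k + 2], ref_id=f"guide_{gene}",
            conserved_divergence=0.005, variable_divergence=0.03,
        )
        refs[f"vertebrate_{gene}"] = derive_relative(
            host, a,
            ("Eukaryota", "Chordata", "Vertebrata", "Bos bloodmealis"),
            sub[k + 3], ref_id=f"vertebrate_{gene}",
            conserved_divergence=0.03, variable_divergence=0.45,
        )
        foreign = derive_relative(
            host, a,
            ("Eukaryota", "Arthropoda", "Arachnida", "Horreolanus parasiticus"),
            sub[k + 4], ref_id=f"foreign_{gene}",
            conserved_divergence=0.04, variable_divergence=0.5,
        )
        refs[foreign.id] = foreign
        refs[f"mite_{gene}"] = derive_relative(
            foreign, a,
            ("Eukaryota", "Arthropoda", "Arachnida", "Horreolanus record"),
            sub[k + 5], ref_id=f"mite_{gene}",
            conserved_divergence=0.05, variable_divergence=0.05,
        )
        k += 6
    return {"architectures": arch, "references": refs}


def blood_specimen_partition(refs: dict[str, ReferenceSequence]) -> LibraryPartition:
    """Insecta library = the host's relative; Non-Insecta = the vertebrate."""
    members = [refs[f"insecta_rel_{g}"] for g in ("LSU", "SSU")]
    members += [refs[f"vertebrate_{g}"] for g in ("LSU", "SSU")]
    return partition_by_node(members, "Insecta")


def blood_specimen_reads(
    seed: int, refs: dict[str, ReferenceSequence],
    n_reads: int = 1600, error_rate: float = 0.01,
) -> list[SimulatedRead]:
    """30% vertebrate blood-meal contamination, 150 nt reads."""
    mix = SpecimenMix(
        host_fraction=0.7,
        contaminants=(("blood", "vertebrate_LSU", 0.15), ("blood", "vertebrate_SSU", 0.15)),
        read_length=150, error_rate=error_rate, n_reads=n_reads, seed=seed,
    )
    return simulate_specimen(mix, refs, host_ref_ids=("host_LSU", "host_SSU"))


def recovery_metrics(
    contigs: Sequence, truth: ReferenceSequence,
    min_contig_length: int = 300, min_identity: float = 97.0,
) -> dict:
    """Coverage of the truth sequence by contig alignments and their
    length-weighted identity.

    Only contigs at >= ``min_identity`` to the truth count as recovering it
    (the same 97% cut that separates host from foreign contigs in
    ``bin_contigs``), so conserved-block contigs assembled from contaminant
    reads do not masquerade as host recovery."""
    covered = np.zeros(len(truth.sequence), dtype=bool)
    w_ident = w_len = 0.0
    for c in contigs:
        if len(c.sequence) < min_contig_length:
            continue
        ident, s, e, _strand = best_alignment_span(c.sequence, truth.sequence)
        if ident < min_identity:
            continue
        covered[s:e] = True
        w_ident += ident * (e - s)
        w_len += e - s
    return {
        "coverage_pct": 100.0 * covered.mean(),
        "identity_pct": (w_ident / w_len) if w_len else 0.0,
    }


def e2e_recovery(seed: int, n_reads: int = 1600) -> dict:
    """Full score -> filter -> assemble -> polish run on the blood-meal
    specimen; recovery of each host gene measured against the simulation
    truth."""
    study = study_references(seed)
    refs = study["references"]
    partition = blood_specimen_partition(refs)
    reads = blood_specimen_reads(seed, refs, n_reads=n_reads)
    scored = score_reads([(r.read_id, r.sequence) for r in reads], partition)
    kept_ids, _ = filter_reads(scored, FilterConfig())
    kept_set = set(kept_ids)
    kept_seqs = [r.sequence for r in reads if r.read_id in kept_set]
    contigs = assemble_reads(kept_seqs, min_overlap=40)
    out = {"n_reads": n_reads, "n_kept": len(kept_ids),
           "summary": summarize(scored, FilterConfig()).as_dict()}
    for gene in ("LSU", "SSU"):
        out[gene] = recovery_metrics(contigs, refs[f"host_{gene}"])
    return out


def filter_benchmark(seed: int, n_reads: int = 800) -> dict:
    """Classifier precision/recall on reads that touch variable blocks.

    Reads wholly inside conserved blocks are inherently ambiguous between
    taxa (the conserved sequence is shared), so only variable-touching
    reads enter the evaluation; for those, the correct action is to retain
    host reads and remove contaminant reads.
    """
    study = study_references(seed)
    refs = study["references"]
    arch = study["architectures"]
    partition = blood_specimen_partition(refs)
    reads = blood_specimen_reads(seed, refs, n_reads=n_reads)
    scored = score_reads([(r.read_id, r.sequence) for r in reads], partition)
    kept_ids, _ = filter_reads(scored, FilterConfig())
    kept = set(kept_ids)
    tp = fp = fn = 0
    for r in reads:
        gene = "LSU" if r.ref_id.endswith("LSU") else "SSU"
        if not read_overlaps_variable_block(r, arch[gene]):
            continue
        is_host = r.origin == "host"
        if r.read_id in kept:
            tp += is_host
            fp += not is_host
        else:
            fn += is_host
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall, "n_evaluated": tp + fp + fn,
            "n_reads": n_reads}


def guided_rescue(seed: int, host_depth: int = 12, foreign_excess: int = 10) -> dict:
    """The parasitised-specimen rescue: host reads plus a water-mite-like
    parasite at ``foreign_excess``-fold the host coverage.

    The host consensus is rebuilt on the conspecific guide with a stringent
    placement threshold (reads must be ~96% identical to their guide
    placement), the parasite's on the mite reference with the default
    threshold; binning against the conspecific separates the two and
    reports the foreign/host coverage ratio.
    """
    study = study_references(seed)
    refs = study["references"]
    host, guide = refs["host_LSU"], refs["guide_LSU"]
    foreign, mite = refs["foreign_LSU"], refs["mite_LSU"]
    L, rl = len(host.sequence), 150
    n_host = int(round(L * host_depth / rl))
    n_foreign = n_host * foreign_excess
    frac_host = n_host / (n_host + n_foreign)
    mix = SpecimenMix(
        host_fraction=frac_host,
        contaminants=(("mite", "foreign_LSU", 1 - frac_host),),
        read_length=rl, error_rate=0.0, n_reads=n_host + n_foreign, seed=seed,
    )
    reads = [r.sequence for r in simulate_specimen(mix, refs, host_ref_ids=("host_LSU",))]
    # first recover the dominant (parasite) consensus on the mite record,
    # then split reads competitively between it and the host guide — the
    # read partitioning a trusted-contig co-assembly achieves
    foreign_contig = guided_consensus(reads, mite, min_depth=2, min_placement_frac=0.7)
    host_reads, foreign_reads = assign_reads_competitively(
        reads, [guide.sequence, foreign_contig.sequence]
    )
    host_contig = guided_consensus(host_reads, guide, min_depth=2, min_placement_frac=0.7)
    foreign_contig = guided_consensus(foreign_reads, mite, min_depth=2,
                                      min_placement_frac=0.7)
    result = bin_contigs([host_contig, foreign_contig], host_reference=guide,
                         host_identity_min=97.0)
    return {
        "host_identity_pct": percent_identity(host_contig.sequence, host.sequence),
        "foreign_identity_pct": percent_identity(foreign_contig.sequence, foreign.sequence),
        "n_host_bin": len(result.host_bin),
        "n_foreign_bin": len(result.foreign_bin),
        "coverage_ratio": result.coverage_ratio_foreign_to_host,
        "n_reads": len(reads),
    }


def coi_roundtrip(seed: int) -> dict:
    """Error-free amplicon pair -> trim -> consensus; exactness vs the
    simulated source interior."""
    sim = simulate_coi_pair(seed, tail_len=15)
    fwd = trim_read(sim.forward)
    rev = trim_read(sim.reverse)
    res = build_consensus(fwd, rev)
    exact = res.sequence == sim.interior
    return {
        "exact": exact,
        "identity_pct": percent_identity(res.sequence, sim.interior, mode="NW"),
        "consensus_length": len(res.sequence),
        "overlap_length": res.overlap_length,
    }


def probe_invariants(seed: int, n_targets: int = 100) -> dict:
    """Coverage and antisense invariants over random targets, both
    remainder policies."""
    from ._seq import revcomp

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    n_ok = 0
    checks = 0
    for i in range(n_targets):
        L = int(rng.integers(80, 1200))
        target = ReferenceSequence(
            f"t{i}", "".join(bases[rng.integers(0, 4, L)]), ("Eukaryota",)
        )
        for policy in ("drop", "right_anchor"):
            probes = tile_probes([target], probe_len=80, remainder_policy=policy)
            covered = np.zeros(L, dtype=bool)
            ok = True
            for p in probes:
                window = target.sequence[p.target_start: p.target_end]
                ok &= p.sequence == revcomp(window)
                covered[p.target_start: p.target_end] = True
            expect = L if policy == "right_anchor" else 80 * (L // 80)
            ok &= int(covered.sum()) == expect
            n_ok += ok
            checks += 1
    return {"fraction_passing": n_ok / checks, "n_targets": n_targets}
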