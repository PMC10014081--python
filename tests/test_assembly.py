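import numpy as np
import pytest

from conftest import random_dna
from oracle_align import revcomp
from ribofilt.assembly import (
    AssemblerSpec,
    Contig,
    assemble_reads,
    assign_reads_competitively,
    bin_contigs,
    correct_reads,
    external_assembler_adapter,
    greedy_assemble,
    guided_consensus,
    parse_contigs_fasta,
    polish_contigs,
    write_contigs_fasta,
)
from ribofilt.reference_library import ReferenceSequence
from ribofilt.synthetic_data import (
    SpecimenMix,
    default_architecture,
    derive_relative,
    make_reference,
    simulate_specimen,
)


def _ref(seq, rid="ref"):
    return ReferenceSequence(rid, seq, ("Eukaryota", "x"))


# --- greedy assembly --------------------------------------------------------

def test_tiling_reads_reconstruct_source(rng):
    source = random_dna(rng, 60)
    reads = [source[0:30], source[20:50], source[30:60]]
    contigs = greedy_assemble(reads, min_overlap=10)
    assert len(contigs) == 1
    c = contigs[0]
    assert c.sequence in (source, revcomp(source))
    assert len(c.per_base_coverage) == 60
    assert c.mean_coverage == pytest.approx(90 / 60)


def test_non_overlapping_reads_stay_singletons(rng):
    a, b = random_dna(rng, 40), random_dna(rng, 40)
    contigs = greedy_assemble([a, b], min_overlap=20)
    assert len(contigs) == 2
    assert {c.sequence if c.sequence in (a, b) else revcomp(c.sequence) for c in contigs} == {a, b}
    assert all(np.all(c.per_base_coverage == 1) for c in contigs)


def test_single_read_is_identity_with_unit_coverage(rng):
    read = random_dna(rng, 50)
    [c] = greedy_assemble([read], min_overlap=10)
    assert c.sequence in (read, revcomp(read))
    assert np.all(c.per_base_coverage == 1)


def test_reverse_complement_reads_are_merged(rng):
    source = random_dna(rng, 80)
    contigs = greedy_assemble([source[:50], revcomp(source[30:])], min_overlap=15)
    assert len(contigs) == 1
    assert contigs[0].sequence in (source, revcomp(source))


def test_greedy_assembly_is_deterministic(rng):
    source = random_dna(rng, 200)
    reads = [source[i: i + 60] for i in range(0, 141, 20)]
    a = greedy_assemble(list(reads), 15)
    b = greedy_assemble(list(reversed(reads)), 15)
    assert sorted(c.sequence for c in a) == sorted(c.sequence for c in b)


# --- read correction --------------------------------------------------------

def test_correct_reads_fixes_isolated_errors(rng):
    source = random_dna(rng, 400)
    reads = [source[i: i + 100] for i in range(0, 301, 10)]
    bad = reads[5]
    flipped = "G" if bad[50] != "G" else "T"
    reads[5] = bad[:50] + flipped + bad[51:]
    corrected = correct_reads(reads, k=21, min_count=3)
    assert corrected[5] == bad
    assert corrected[:5] == reads[:5]


# --- guided consensus -------------------------------------------------------

def _guided_fixture(seed, error_rate=0.0, depth=20):
    arch = default_architecture("LSU")
    host = make_reference(arch, seed, "host", ("Eukaryota", "Insecta", "host sp"))
    guide = derive_relative(host, arch, ("Eukaryota", "Insecta", "guide sp"), seed + 1,
                            ref_id="guide", conserved_divergence=0.01,
                            variable_divergence=0.03)
    n = int(len(host.sequence) * depth / 150)
    mix = SpecimenMix(host_fraction=1.0, read_length=150, error_rate=error_rate,
                      n_reads=n, seed=seed)
    reads = [r.sequence for r in simulate_specimen(mix, {"host": host}, ("host",))]
    return host, guide, reads


def test_guided_consensus_recovers_source_from_related_guide():
    host, guide, reads = _guided_fixture(11, error_rate=0.0, depth=20)
    contig = guided_consensus(reads, guide, min_depth=2)
    assert contig.mode == "guided" and contig.guide_id == "guide"
    # every adequately covered column equals the true source; columns that
    # fell back to the guide (uniform read starts under-cover the termini)
    # are exactly the flagged low-depth ones
    low = set(contig.low_depth_positions)
    mismatches = {
        i for i, (a, b) in enumerate(zip(contig.sequence, host.sequence)) if a != b
    }
    assert mismatches <= low
    assert len(contig.sequence) == len(host.sequence)
    from ribofilt._seq import percent_identity

    assert percent_identity(contig.sequence, host.sequence) >= 99.5
    assert len(contig.per_base_coverage) == len(contig.sequence)


def test_guided_consensus_with_errors_stays_accurate():
    from ribofilt._seq import percent_identity

    host, guide, reads = _guided_fixture(12, error_rate=0.01, depth=30)
    contig = guided_consensus(reads, guide, min_depth=2)
    assert percent_identity(contig.sequence, host.sequence) >= 99.5


def test_guided_consensus_empty_reads_errors():
    guide = _ref("ACGT" * 100)
    with pytest.raises(ValueError):
        guided_consensus([], guide)


def test_guided_consensus_unrelated_reads_errors(rng):
    guide = _ref(random_dna(rng, 500))
    reads = [random_dna(rng, 150) for _ in range(5)]
    with pytest.raises(ValueError, match="unrelated"):
        guided_consensus(reads, guide, min_placement_frac=0.9)


def test_guided_consensus_idempotent_on_its_own_output():
    host, guide, reads = _guided_fixture(13, error_rate=0.0, depth=20)
    first = guided_consensus(reads, guide, min_depth=2)
    again = guided_consensus(
        reads, ReferenceSequence("first", first.sequence, ("Eukaryota", "x")), min_depth=2
    )
    assert again.sequence == first.sequence


def test_competitive_assignment_splits_by_best_template(rng):
    a, b = random_dna(rng, 500), random_dna(rng, 500)
    reads_a = [a[i: i + 100] for i in range(0, 400, 40)]
    reads_b = [b[i: i + 100] for i in range(0, 400, 40)]
    bin_a, bin_b = assign_reads_competitively(reads_a + reads_b, [a, b])
    assert sorted(bin_a) == sorted(reads_a)
    assert sorted(bin_b) == sorted(reads_b)


# --- binning ----------------------------------------------------------------

def _contig(seq, cov, cid="c"):
    return Contig(cid, seq, np.full(len(seq), float(cov)))


def test_bin_contigs_separates_by_identity_with_coverage_ratio(rng):
    arch = default_architecture("SSU")
    host = make_reference(arch, 5, "host")
    near = derive_relative(host, arch, ("Eukaryota",), 6, conserved_divergence=0.005,
                           variable_divergence=0.01)        # ~99% identity
    far = derive_relative(host, arch, ("Eukaryota",), 7, conserved_divergence=0.05,
                          variable_divergence=0.05)         # ~95% identity
    res = bin_contigs(
        [_contig(near.sequence, 10, "near"), _contig(far.sequence, 100, "far")],
        host_reference=host,
    )
    assert [c.id for c in res.host_bin] == ["near"]
    assert [c.id for c in res.foreign_bin] == ["far"]
    assert res.coverage_ratio_foreign_to_host == pytest.approx(10.0)


def test_bin_contigs_identical_contig_goes_to_host(rng):
    seq = random_dna(rng, 400)
    res = bin_contigs([_contig(seq, 5)], host_reference=_ref(seq))
    assert len(res.host_bin) == 1 and not res.foreign_bin


def test_bin_contigs_all_foreign_leaves_host_empty(rng):
    res = bin_contigs([_contig(random_dna(rng, 400), 5)],
                      host_reference=_ref(random_dna(rng, 400)))
    assert not res.host_bin and len(res.foreign_bin) == 1


def test_bin_contigs_conserves_contigs(rng):
    contigs = [_contig(random_dna(rng, 300), i + 1, f"c{i}") for i in range(6)]
    res = bin_contigs(contigs, host_reference=_ref(contigs[0].sequence))
    assert len(res.host_bin) + len(res.foreign_bin) == 6


# --- serialization + external adapter --------------------------------------

def test_contigs_fasta_round_trip(tmp_path, rng):
    source = random_dna(rng, 120)
    contigs = greedy_assemble([source[:70], source[40:]], 20)
    path = tmp_path / "contigs.fasta"
    write_contigs_fasta(contigs, path)
    back = parse_contigs_fasta(path)
    assert [(c.id, c.sequence) for c in back] == [(c.id, c.sequence) for c in contigs]
    assert [c.mean_coverage for c in back] == pytest.approx(
        [c.mean_coverage for c in contigs], rel=1e-4
    )


def test_spades_header_dialect_parsed(tmp_path):
    path = tmp_path / "contigs.fasta"
    path.write_text(">NODE_1_length_200_cov_12.5\n" + "ACGT" * 50 + "\n")
    [c] = parse_contigs_fasta(path)
    assert c.id == "NODE_1"
    assert c.mean_coverage == pytest.approx(12.5)


def test_external_adapter_missing_binary_names_fallback(tmp_path):
    reads = tmp_path / "reads.fasta"
    reads.write_text(">r1\nACGTACGT\n")
    with pytest.raises(FileNotFoundError, match="greedy_assemble"):
        external_assembler_adapter(reads, AssemblerSpec(),
                                   binary="definitely_not_installed_asm")


def test_assembler_spec_rejects_even_or_unsorted_kmers():
    with pytest.raises(ValueError):
        AssemblerSpec(kmer_lengths=(30, 51, 71))
    with pytest.raises(ValueError):
        AssemblerSpec(kmer_lengths=(71, 51, 31))
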