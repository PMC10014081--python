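import numpy as np
import pytest

from oracle_align import revcomp
from ribofilt.coi_barcode import HCO2198, LCO1490, build_consensus, trim_read
from ribofilt.synthetic_data import (
    RrnaArchitecture,
    SpecimenMix,
    default_architecture,
    derive_relative,
    make_reference,
    read_overlaps_variable_block,
    simulate_coi_pair,
    simulate_specimen,
)


def test_default_gene_lengths():
    lsu = make_reference(default_architecture("LSU"), 1)
    ssu = make_reference(default_architecture("SSU"), 1)
    assert len(lsu.sequence) == 3_900
    assert len(ssu.sequence) == 1_900


def test_make_reference_deterministic_under_seed():
    arch = default_architecture("SSU")
    assert make_reference(arch, 5).sequence == make_reference(arch, 5).sequence
    assert make_reference(arch, 5).sequence != make_reference(arch, 6).sequence


def test_architecture_blocks_must_sum():
    with pytest.raises(ValueError):
        RrnaArchitecture("LSU", 100, (("conserved", 60), ("variable", 30)))


def test_zero_conserved_divergence_keeps_conserved_blocks_identical():
    arch = default_architecture("SSU", conserved_divergence=0.0)
    base = make_reference(arch, 2)
    rel = derive_relative(base, arch, ("Eukaryota",), 3)
    for kind, s, e in arch.block_spans():
        if kind == "conserved":
            assert rel.sequence[s:e] == base.sequence[s:e]
        else:
            assert rel.sequence[s:e] != base.sequence[s:e]


def test_variable_block_divergence_within_binomial_bound():
    arch = RrnaArchitecture("SSU", 400, (("variable", 400),),
                            conserved_divergence=0.0, variable_divergence=0.2)
    base = make_reference(arch, 4)
    rel = derive_relative(base, arch, ("Eukaryota",), 5)
    diffs = sum(a != b for a, b in zip(base.sequence, rel.sequence))
    mean, sd = 400 * 0.2, (400 * 0.2 * 0.8) ** 0.5
    assert abs(diffs - mean) <= 3 * sd


def test_overall_identity_between_block_weighted_extremes():
    arch = default_architecture("SSU", conserved_divergence=0.02,
                                variable_divergence=0.2)
    base = make_reference(arch, 6)
    rel = derive_relative(base, arch, ("Eukaryota",), 7)
    ident = np.mean([a == b for a, b in zip(base.sequence, rel.sequence)])
    assert 0.8 <= ident <= 0.98


def test_pure_host_error_free_reads_are_exact_substrings():
    arch = default_architecture("SSU")
    host = make_reference(arch, 8, "host")
    mix = SpecimenMix(host_fraction=1.0, read_length=150, error_rate=0.0,
                      n_reads=50, seed=9)
    for r in simulate_specimen(mix, {"host": host}, ("host",)):
        window = r.sequence if r.strand == "+" else revcomp(r.sequence)
        assert window == host.sequence[r.start: r.start + 150]
        assert r.origin == "host"


def test_host_fraction_within_binomial_bound():
    arch = default_architecture("SSU")
    host = make_reference(arch, 10, "host")
    other = make_reference(arch, 11, "other")
    mix = SpecimenMix(host_fraction=0.7, contaminants=(("blood", "other", 0.3),),
                      read_length=150, error_rate=0.0, n_reads=10_000, seed=12)
    reads = simulate_specimen(mix, {"host": host, "other": other}, ("host",))
    n_host = sum(r.origin == "host" for r in reads)
    mean, sd = 7000, (10_000 * 0.7 * 0.3) ** 0.5
    assert abs(n_host - mean) <= 3 * sd


def test_specimen_deterministic_under_seed():
    arch = default_architecture("SSU")
    host = make_reference(arch, 13, "host")
    mix = SpecimenMix(host_fraction=1.0, n_reads=30, seed=14)
    a = simulate_specimen(mix, {"host": host}, ("host",))
    b = simulate_specimen(mix, {"host": host}, ("host",))
    assert a == b


def test_fractions_must_sum_to_one():
    with pytest.raises(ValueError):
        SpecimenMix(host_fraction=0.5, contaminants=(("blood", "x", 0.3),))


def test_reference_shorter_than_read_length_is_an_error():
    from ribofilt.reference_library import ReferenceSequence

    short = ReferenceSequence("short", "ACGT" * 10, ("Eukaryota",))
    mix = SpecimenMix(host_fraction=1.0, read_length=150, n_reads=5, seed=1)
    with pytest.raises(ValueError, match="short"):
        simulate_specimen(mix, {"short": short}, ("short",))


def test_variable_block_overlap_classification():
    arch = default_architecture("LSU")        # first blocks: conserved 300, variable 200
    mk = lambda start: type("R", (), {"start": start, "sequence": "A" * 150})()
    assert not read_overlaps_variable_block(mk(0), arch)
    assert read_overlaps_variable_block(mk(200), arch)
    assert read_overlaps_variable_block(mk(320), arch)


# --- COI pair ---------------------------------------------------------------

def test_coi_source_length_and_primer_ends():
    sim = simulate_coi_pair(1)
    assert len(sim.source) == 658
    assert sim.source.startswith(LCO1490)
    assert sim.source.endswith(revcomp(HCO2198))


def test_coi_pair_deterministic():
    assert simulate_coi_pair(3) == simulate_coi_pair(3)
    assert simulate_coi_pair(3) != simulate_coi_pair(4)


def test_coi_span_too_short_is_an_error():
    with pytest.raises(ValueError):
        simulate_coi_pair(1, read_span=300)


def test_coi_roundtrip_with_quality_tails():
    sim = simulate_coi_pair(2, tail_len=20)
    fwd, rev = trim_read(sim.forward), trim_read(sim.reverse)
    assert fwd.sequence.startswith("TTTTGG")
    res = build_consensus(fwd, rev)
    assert res.sequence == sim.interior
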