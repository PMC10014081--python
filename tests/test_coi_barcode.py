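import pytest

from oracle_align import revcomp
from ribofilt.coi_barcode import (
    SangerRead,
    assign_species,
    build_consensus,
    trim_read,
)


# --- trimming ---------------------------------------------------------------

def test_forward_anchor_trim():
    read = SangerRead("forward", "AAAATTTTGGCCGG")
    assert trim_read(read).sequence == "TTTTGGCCGG"


def test_reverse_anchor_n_wildcard():
    read = SangerRead("reverse", "CCCGGATCTAAAA")
    assert trim_read(read).sequence == "GGATCTAAAA"


def test_quality_trim_precedes_anchoring():
    seq = "TTTTGGACGTAC"
    quals = (40,) * 10 + (20, 20)
    trimmed = trim_read(SangerRead("forward", seq, quals))
    assert trimmed.sequence == "TTTTGGACGT"
    assert trimmed.qualities == (40,) * 10


def test_trim_is_idempotent():
    read = SangerRead("forward", "AAAATTTTGGCCGG" + "ACGT" * 5,
                      (15, 15) + (40,) * 32)
    once = trim_read(read)
    assert trim_read(once) == once


def test_missing_anchor_is_an_error():
    with pytest.raises(ValueError, match="anchor"):
        trim_read(SangerRead("forward", "ACGTACGTACGT"))


# --- consensus --------------------------------------------------------------

def _pair_from_source(source, span, fq=None, rq=None):
    fwd = SangerRead("forward", source[:span], fq)
    rev = SangerRead("reverse", revcomp(source[-span:]), rq)
    return fwd, rev


def test_consensus_reconstructs_known_source(rng):
    from conftest import random_dna

    source = "TTTTGG" + random_dna(rng, 615)      # 621 nt, anchored
    fwd, rev = _pair_from_source(source, 400)
    res = build_consensus(fwd, rev)
    assert res.sequence == source
    assert res.complete
    assert res.overlap_length == 179
    assert res.n_disagreements == 0


def test_identical_reads_give_that_sequence(rng):
    from conftest import random_dna

    seq = random_dna(rng, 300)
    res = build_consensus(SangerRead("forward", seq),
                          SangerRead("reverse", revcomp(seq)))
    assert res.sequence == seq
    assert not res.complete        # below the configured 621 nt


def test_disagreement_resolved_by_higher_quality():
    base = "ACGTACGTACGTACGTACGTACGTACGTAC"      # 30 nt
    mutated = base[:14] + ("G" if base[14] != "G" else "T") + base[15:]
    fq = tuple([40] * 30)
    rq_high = tuple([50] * 30)
    # reverse read carries the variant with higher quality -> variant wins
    res = build_consensus(
        SangerRead("forward", base, fq),
        SangerRead("reverse", revcomp(mutated), rq_high),
        min_overlap_identity=90.0,
    )
    assert res.sequence == mutated
    # equal qualities -> forward base wins
    res = build_consensus(
        SangerRead("forward", base, fq),
        SangerRead("reverse", revcomp(mutated), fq),
        min_overlap_identity=90.0,
    )
    assert res.sequence == base


def test_discordant_pair_is_an_error(rng):
    from conftest import random_dna

    with pytest.raises(ValueError, match="discordant"):
        build_consensus(SangerRead("forward", random_dna(rng, 200)),
                        SangerRead("reverse", random_dna(rng, 200)))


def test_consensus_symmetric_under_role_swap(rng):
    from conftest import random_dna

    source = random_dna(rng, 500)
    fq = tuple([40] * 350)
    fwd, rev = _pair_from_source(source, 350, fq, fq)
    a = build_consensus(fwd, rev, target_length=10**9)
    swapped_fwd = SangerRead("forward", rev.sequence, fq)
    swapped_rev = SangerRead("reverse", fwd.sequence, fq)
    b = build_consensus(swapped_fwd, swapped_rev, target_length=10**9)
    assert b.sequence == revcomp(a.sequence)


# --- species assignment -----------------------------------------------------

def test_revision_to_clear_best_hit():
    # morphology said one species; the barcode matches another at 97-100%
    # while the morphological species' sister taxa sit at ~90%
    call = assign_species(
        "Aedes opok",
        [("Aedes simpsoni", 100.0), ("Aedes simpsoni", 97.0),
         ("Aedes luteocephalus", 90.0), ("Aedes africanus", 89.0)],
    )
    assert call.status == "revised"
    assert call.species == "Aedes simpsoni"


def test_single_nucleotide_sister_species_is_ambiguous():
    call = assign_species(
        "Culex quinquefasciatus",
        [("Culex pipiens", 99.84), ("Culex quinquefasciatus", 99.68)],
    )
    assert call.status == "ambiguous_sister_species"
    assert call.display_name == "Culex quinquefasciatus"


def test_all_hits_below_threshold_in_one_genus_gives_genus_only():
    call = assign_species(
        "Culex duttoni",
        [("Culex neavei", 93.0), ("Culex perexiguus", 92.5), ("Culex antennatus", 91.0)],
    )
    assert call.status == "genus_only"
    assert call.genus == "Culex"
    assert call.species is None
    assert call.display_name == "Culex sp."


def test_matching_top_hit_confirms_morphology():
    call = assign_species(
        "Aedes albopictus",
        [("Aedes albopictus", 99.5), ("Aedes aegypti", 93.0)],
    )
    assert call.status == "confirmed"
    assert call.species == "Aedes albopictus"


def test_small_margin_retains_morphological_identity():
    call = assign_species(
        "Culex tritaeniorhynchus",
        [("Culex vishnui", 98.0), ("Culex tritaeniorhynchus", 97.0)],
    )
    assert call.status == "ambiguous_sister_species"
    assert call.display_name == "Culex tritaeniorhynchus"


def test_no_hits_with_morphology_gives_no_reference():
    call = assign_species("Anopheles baezai", [])
    assert call.status == "no_reference"


def test_empty_hits_without_morphology_is_an_error():
    with pytest.raises(ValueError):
        assign_species(None, [])


def test_equal_identity_hits_order_invariant():
    hits = [("Culex neavei", 96.0), ("Culex perexiguus", 96.0)]
    a = assign_species("Culex neavei", hits)
    b = assign_species("Culex neavei", list(reversed(hits)))
    assert a.status == b.status == "ambiguous_sister_species"
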