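"""Two-partition (Insecta / Non-Insecta) rRNA reference library.

The filtration strategy cuts a taxonomy-annotated rRNA database (SILVA-style
headers: ``>ID Rank1;Rank2;...;Leaf``) into two disjoint sets at a chosen
anchor node of the taxonomic tree — by default ``Insecta``. Reads are later
scored against both sets and classified by the ratio of their best scores.
Because public databases hold few complete insect rRNA genes, the Insecta
side can be augmented across filtration cycles with full-length sequences
assembled in earlier cycles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Union

from Bio import SeqIO

from ._seq import normalize

PathOrHandle = Union[str, Path, IO[str]]

DEFAULT_ANCHOR = "Insecta"


@dataclass(frozen=True)
class ReferenceSequence:
    """One rRNA reference: opaque id, DNA sequence, root-to-leaf taxonomy."""

    id: str
    sequence: str
    taxonomy: tuple[str, ...]

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"reference {self.id!r}: empty sequence")
        if not self.taxonomy:
            raise ValueError(f"reference {self.id!r}: empty taxonomy")
        object.__setattr__(self, "taxonomy", tuple(self.taxonomy))

    def header(self) -> str:
        return f"{self.id} {';'.join(self.taxonomy)}"


@dataclass(frozen=True)
class LibraryPartition:
    """Disjoint Insecta / Non-Insecta reference sets plus the anchor node.

    ``cycle`` counts augmentation rounds (0 for a freshly cut partition).
    """

    anchor_node: str
    insecta: dict[str, ReferenceSequence]
    non_insecta: dict[str, ReferenceSequence]
    cycle: int = 0

    def __post_init__(self):
        overlap = self.insecta.keys() & self.non_insecta.keys()
        if overlap:
            raise ValueError(f"partition not disjoint; shared ids {sorted(overlap)[:5]}")
        for rec in self.non_insecta.values():
            if self.anchor_node in rec.taxonomy:
                raise ValueError(
                    f"{rec.id!r} carries anchor {self.anchor_node!r} but sits in non_insecta"
                )

    @property
    def n_insecta(self) -> int:
        return len(self.insecta)

    @property
    def n_non_insecta(self) -> int:
        return len(self.non_insecta)


def parse_taxonomy_fasta(source: PathOrHandle) -> list[ReferenceSequence]:
    """Parse FASTA whose headers carry a semicolon-delimited taxonomy.

    The taxonomy string is everything after the first whitespace of the
    header, split on ``;`` with surrounding whitespace stripped. U is mapped
    to T so RNA-alphabet databases share one alphabet with DNA reads. A
    header without a taxonomy string is an error — records are never bucketed
    silently.
    """
    records: list[ReferenceSequence] = []
    for rec in SeqIO.parse(_as_handle(source), "fasta"):
        if not rec.seq:
            raise ValueError(f"record {rec.id!r}: empty sequence")
        parts = rec.description.split(None, 1)
        if len(parts) < 2:
            raise ValueError(f"record {rec.id!r}: header has no taxonomy string")
        taxonomy = tuple(t.strip() for t in parts[1].split(";") if t.strip())
        if not taxonomy:
            raise ValueError(f"record {rec.id!r}: header has no taxonomy string")
        seq = normalize(str(rec.seq), context=f"record {rec.id!r}")
        records.append(ReferenceSequence(rec.id, seq, taxonomy))
    return records


def partition_by_node(
    records: Iterable[ReferenceSequence], anchor_node: str = DEFAULT_ANCHOR
) -> LibraryPartition:
    """Cut records into insecta / non_insecta at *anchor_node*.

    A record lands on the insecta side iff the anchor equals one of its
    taxonomy ranks exactly — substring hits (e.g. "Insectarium") do not
    count. Duplicate ids with identical sequences collapse; conflicting
    duplicates are an error.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to partition")
    insecta: dict[str, ReferenceSequence] = {}
    non_insecta: dict[str, ReferenceSequence] = {}
    for rec in records:
        bucket = insecta if anchor_node in rec.taxonomy else non_insecta
        prev = insecta.get(rec.id) or non_insecta.get(rec.id)
        if prev is not None:
            if prev.sequence != rec.sequence:
                raise ValueError(f"duplicate id {rec.id!r} with conflicting sequences")
            continue
        bucket[rec.id] = rec
    return LibraryPartition(anchor_node, insecta, non_insecta, cycle=0)


def augment_insecta(
    partition: LibraryPartition, new_sequences: Iterable[ReferenceSequence]
) -> LibraryPartition:
    """Add assembled sequences to the Insecta side; one filtration cycle.

    Novel sequences whose taxonomy lacks the anchor are re-annotated as
    ``(anchor, "assembled", <id>)`` so the partition invariant holds.
    Re-adding an identical (id, sequence) pair is idempotent; an id collision
    with a different sequence — on either side — is an error.
    """
    insecta = dict(partition.insecta)
    for rec in new_sequences:
        prev = partition.insecta.get(rec.id) or partition.non_insecta.get(rec.id)
        if prev is not None:
            if prev.sequence != rec.sequence:
                raise ValueError(f"id collision on {rec.id!r} with a different sequence")
            continue
        if partition.anchor_node not in rec.taxonomy:
            rec = replace(rec, taxonomy=(partition.anchor_node, "assembled", rec.id))
        insecta[rec.id] = rec
    return LibraryPartition(
        partition.anchor_node, insecta, dict(partition.non_insecta), partition.cycle + 1
    )


def write_partition(partition: LibraryPartition, outdir: str | Path) -> dict:
    """Write insecta.fasta / non_insecta.fasta plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, bucket in (("insecta", partition.insecta), ("non_insecta", partition.non_insecta)):
        with open(outdir / f"{name}.fasta", "w") as fh:
            for rec in bucket.values():
                fh.write(f">{rec.header()}\n{rec.sequence}\n")
    manifest = {
        "anchor_node": partition.anchor_node,
        "n_insecta": partition.n_insecta,
        "n_non_insecta": partition.n_non_insecta,
        "cycle": partition.cycle,
    }
    with open(outdir / "partition_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_partition(
    insecta_fasta: PathOrHandle,
    non_insecta_fasta: PathOrHandle,
    anchor_node: str = DEFAULT_ANCHOR,
    cycle: int = 0,
) -> LibraryPartition:
    """Rebuild a partition from the two FASTA files written by write_partition."""
    ins = {r.id: r for r in parse_taxonomy_fasta(insecta_fasta)}
    non = {r.id: r for r in parse_taxonomy_fasta(non_insecta_fasta)}
    return LibraryPartition(anchor_node, ins, non, cycle=cycle)


def _as_handle(source: PathOrHandle):
    if isinstance(source, (str, Path)):
        return str(source)
    return source
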