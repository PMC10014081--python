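"""Tiled antisense DNA probes for hybridisation-based rRNA depletion.

Depletion by probe hybridisation + RNase H digestion needs DNA oligos
antisense to the target rRNA. This module tiles each target with
non-overlapping windows of a fixed probe length (80 nt by default) and
emits the reverse complement of each window. When the target length is not
a multiple of the probe length, the remainder is either dropped or covered
by a final right-anchored probe that overlaps its predecessor
(``right_anchor``, the default — full coverage of the variable 3' end
matters for depletion).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._seq import revcomp
from .reference_library import ReferenceSequence

DEFAULT_PROBE_LENGTH = 80
DEFAULT_POOL_CONCENTRATION_UM = 0.04


@dataclass(frozen=True)
class Probe:
    """An antisense probe over target[target_start:target_end) (sense coords)."""

    id: str
    sequence: str
    target_id: str
    target_start: int
    target_end: int

    def __post_init__(self):
        if self.target_end - self.target_start != len(self.sequence):
            raise ValueError(f"probe {self.id}: window length != probe length")


def tile_probes(
    targets: Iterable[ReferenceSequence],
    probe_len: int = DEFAULT_PROBE_LENGTH,
    remainder_policy: str = "right_anchor",
) -> list[Probe]:
    """Tile every target with antisense probes of ``probe_len``.

    Windows are [0,L), [L,2L), ...; with ``right_anchor`` a final window
    [len-L, len) is added when the length is not a multiple of L (it
    overlaps the previous window). ``drop`` discards the remainder.
    """
    if probe_len < 1:
        raise ValueError("probe_len must be >= 1")
    if remainder_policy not in ("drop", "right_anchor"):
        raise ValueError("remainder_policy must be 'drop' or 'right_anchor'")
    probes: list[Probe] = []
    for target in targets:
        L = len(target.sequence)
        if L < probe_len:
            raise ValueError(f"target {target.id!r} shorter than probe length {probe_len}")
        starts = list(range(0, L - probe_len + 1, probe_len))
        if remainder_policy == "right_anchor" and L % probe_len != 0:
            starts.append(L - probe_len)
        for n, s in enumerate(starts, start=1):
            window = target.sequence[s: s + probe_len]
            probes.append(
                Probe(f"{target.id}_probe_{n:03d}", revcomp(window), target.id, s, s + probe_len)
            )
    return probes


def probe_pool_manifest(
    probes: Sequence[Probe],
    pool_concentration_um: float | None = None,
) -> pd.DataFrame:
    """Order-sheet rows: one per probe plus pool metadata columns.

    Duplicate probe sequences (possible when targets share exact blocks) are
    flagged in the ``duplicate_of`` column.
    """
    if not probes:
        raise ValueError("no probes")
    if pool_concentration_um is None:
        pool_concentration_um = DEFAULT_POOL_CONCENTRATION_UM
    seen: dict[str, str] = {}
    rows = []
    for p in probes:
        dup = seen.get(p.sequence, "")
        if not dup:
            seen[p.sequence] = p.id
        rows.append(
            {
                "probe_id": p.id,
                "sequence_5to3": p.sequence,
                "target_id": p.target_id,
                "target_start": p.target_start,
                "target_end": p.target_end,
                "pool_concentration_um": pool_concentration_um,
                "duplicate_of": dup,
            }
        )
    return pd.DataFrame(rows)


def write_probe_fasta(probes: Sequence[Probe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.id} {p.target_id}:{p.target_start}-{p.target_end}\n{p.sequence}\n")


def write_order_sheet(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)
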