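"""The iterative filtration/assembly pipeline and its flat-file config.

Each cycle scores reads against the current two-partition library, filters
them on the ratio of scores, assembles the kept reads, and adds any
full-length contigs to the Insecta side before the next cycle — the
compensation for reference databases holding few complete insect rRNA
genes. Cycling stops at the configured cap or as soon as the kept read set
stops changing (a fixpoint: nothing new would be assembled).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .assembly import Contig, assemble_reads, write_contigs_fasta
from .ratio_filter import (
    FilterConfig,
    filter_reads,
    ratio_histogram,
    summarize,
    write_histogram_tsv,
    write_summary_json,
)
from .read_scoring import ScoringParams, score_reads, write_scores_tsv
from .reference_library import (
    ReferenceSequence,
    augment_insecta,
    load_partition,
    write_partition,
)

log = logging.getLogger("ribofilt")


@dataclass
class PipelineConfig:
    reads: str
    insecta_fasta: str
    non_insecta_fasta: str
    outdir: str
    scoring: ScoringParams = field(default_factory=ScoringParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_overlap: int = 40
    polish: bool = True
    augment_min_length: int = 1000
    cycles: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")

    def validate_paths(self) -> None:
        for p in (self.reads, self.insecta_fasta, self.non_insecta_fasta):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


def load_reads(path: str | Path) -> list[tuple[str, str]]:
    """FASTA or FASTQ reads (qualities ignored), format by extension."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_kept_reads(reads, kept_ids, path: str | Path) -> None:
    kept = set(kept_ids)
    with open(path, "w") as fh:
        for rid, seq in reads:
            if rid in kept:
                fh.write(f">{rid}\n{seq}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute score -> filter -> assemble for ``config.cycles`` rounds with
    Insecta-library augmentation in between; returns (and writes) the run
    manifest."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = load_reads(config.reads)
    if not reads:
        raise RuntimeError(f"stage load (cycle 0): no reads in {config.reads}")
    partition = load_partition(config.insecta_fasta, config.non_insecta_fasta)
    manifest: dict = {
        "parameters": {
            "scoring": dataclasses.asdict(config.scoring),
            "threshold": config.filter.threshold,
            "inclusive": config.filter.inclusive,
            "min_overlap": config.min_overlap,
            "polish": config.polish,
            "augment_min_length": config.augment_min_length,
            "cycles": config.cycles,
            "seed": config.seed,
        },
        "n_reads": len(reads),
        "cycles": [],
        "converged": False,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    prev_kept: Optional[frozenset] = None
    contigs: list[Contig] = []
    for cycle in range(1, config.cycles + 1):
        stage = "score"
        try:
            scored = score_reads(reads, partition, config.scoring)
            stage = "filter"
            kept_ids, _ = filter_reads(scored, config.filter)
            summary = summarize(scored, config.filter)
            stage = "assemble"
            kept_seqs = [seq for rid, seq in reads if rid in set(kept_ids)]
            contigs = assemble_reads(kept_seqs, config.min_overlap, polish=config.polish)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed in cycle {cycle}: {exc}") from exc

        cyc_dir = outdir / f"cycle_{cycle}"
        cyc_dir.mkdir(exist_ok=True)
        write_scores_tsv(scored, cyc_dir / "scores.tsv")
        write_summary_json(summary, cyc_dir / "filter_summary.json")
        write_histogram_tsv(ratio_histogram(scored, 40, 2.0), cyc_dir / "ratio_histogram.tsv")
        write_kept_reads(reads, kept_ids, cyc_dir / "kept_reads.fasta")
        write_contigs_fasta(contigs, cyc_dir / "contigs.fasta")

        full_length = [c for c in contigs if len(c) >= config.augment_min_length]
        manifest["cycles"].append(
            {
                "cycle": cycle,
                "filter_summary": summary.as_dict(),
                "n_contigs": len(contigs),
                "n_full_length": len(full_length),
                "max_contig_length": max((len(c) for c in contigs), default=0),
                "library": {"insecta": partition.n_insecta,
                            "non_insecta": partition.n_non_insecta},
            }
        )
        log.info("cycle %d: kept %d/%d reads, %d contigs (%d full-length)",
                 cycle, len(kept_ids), len(reads), len(contigs), len(full_length))

        kept_now = frozenset(kept_ids)
        if prev_kept is not None and kept_now == prev_kept:
            manifest["converged"] = True
            log.info("kept read set unchanged; stopping after cycle %d", cycle)
            break
        prev_kept = kept_now
        if cycle < config.cycles and full_length:
            partition = augment_insecta(
                partition,
                [ReferenceSequence(f"cycle{cycle}_{c.id}", c.sequence,
                                   (partition.anchor_node, "assembled", c.id))
                 for c in full_length],
            )
    manifest["final_cycle"] = manifest["cycles"][-1]["cycle"]
    write_partition(partition, outdir / "final_library")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# --- flat key=value config files -------------------------------------------

_CONFIG_KEYS = {
    "reads": str, "insecta_fasta": str, "non_insecta_fasta": str, "outdir": str,
    "match_reward": int, "mismatch_penalty": int, "gap_open": int,
    "gap_extend": int, "min_report_score": int,
    "threshold": float, "inclusive": lambda v: v.lower() in ("1", "true", "yes"),
    "min_overlap": int, "polish": lambda v: v.lower() in ("1", "true", "yes"),
    "augment_min_length": int, "cycles": int, "seed": int,
}


def parse_config_file(path: str | Path) -> dict:
    """Flat ``key = value`` lines; '#' comments and blank lines ignored."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = _CONFIG_KEYS[key](val)
    return values


def config_from_values(values: dict) -> PipelineConfig:
    scoring_keys = ("match_reward", "mismatch_penalty", "gap_open",
                    "gap_extend", "min_report_score")
    scoring = ScoringParams(**{k: values[k] for k in scoring_keys if k in values})
    filt = FilterConfig(
        threshold=values.get("threshold", 0.8),
        inclusive=values.get("inclusive", True),
    )
    missing = [k for k in ("reads", "insecta_fasta", "non_insecta_fasta", "outdir")
               if k not in values]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    return PipelineConfig(
        reads=values["reads"],
        insecta_fasta=values["insecta_fasta"],
        non_insecta_fasta=values["non_insecta_fasta"],
        outdir=values["outdir"],
        scoring=scoring,
        filter=filt,
        min_overlap=values.get("min_overlap", 40),
        polish=values.get("polish", True),
        augment_min_length=values.get("augment_min_length", 1000),
        cycles=values.get("cycles", 1),
        seed=values.get("seed", 0),
    )
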