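"""Benchmark construction: implant reference motifs into flanking context.

The pipeline mirrors how evaluation datasets for structural motif discovery
are built from a curated seed alignment: each row's motif (sequence plus
projected consensus structure) is extracted, rows whose motif also occurs
reverse-complemented are removed, at most a fixed number of rows is sampled
at random, the motif is embedded in flanking sequence randomly split
between the 5' and 3' ends, and any record still containing ambiguity
letters is discarded.  Every record carries its truth: the motif
coordinates within the full sequence and the motif-local structure.

Real genomic context retrieval is replaced by user-provided context
sequences or by synthetic flanks drawn from a seeded generator, so the
whole pipeline is reproducible offline from the seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CANONICAL_BASES, RnaSequence, SecondaryStructure, parse_dbn
from .formats import SeedAlignment, project_consensus, write_fasta
from .loops import classify_tier, complexity_profile

__all__ = [
    "BenchmarkRecord",
    "GeneratorConfig",
    "EmptyBenchmarkError",
    "generate",
    "split_flanks",
    "ambiguity_filter",
    "reverse_complement",
    "reverse_complement_filter",
    "write_benchmark",
    "read_manifest",
]

_RC = str.maketrans("ACGU", "UGCA")


class EmptyBenchmarkError(RuntimeError):
    """No sequences survived the filters."""


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark sequence with its implanted-motif truth.

    ``motif_start``/``motif_end`` are 1-based inclusive positions in the
    full sequence; ``structure`` is in motif-local coordinates (position 1
    = ``motif_start``).
    """

    identifier: str
    sequence: RnaSequence
    motif_start: int
    motif_end: int
    structure: SecondaryStructure
    source_row: str
    family: str

    def __post_init__(self) -> None:
        if self.motif_end - self.motif_start + 1 != self.structure.n:
            raise ValueError(
                "motif span and truth-structure length disagree: "
                f"{self.motif_end - self.motif_start + 1} vs {self.structure.n}"
            )
        if not (1 <= self.motif_start <= self.motif_end <= len(self.sequence)):
            raise ValueError("motif coordinates outside the full sequence")

    @property
    def motif_sequence(self) -> str:
        return self.sequence.residues[self.motif_start - 1: self.motif_end]

    def absolute_truth_pairs(self) -> frozenset:
        """Truth pairs in full-sequence coordinates."""
        offset = self.motif_start - 1
        return frozenset(p.shifted(offset, offset) for p in self.structure.pairs)


@dataclass(frozen=True)
class GeneratorConfig:
    """Benchmark-generation settings; the defaults are the study conditions
    (200 nt of flanking sequence, at most 50 sequences per family)."""

    flank_total: int = 200
    max_per_family: int = 50
    seed: int = 0
    flank_source: str = "synthetic"  # "synthetic" or "context"
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rc_filter: bool = True
    discard_ambiguous: bool = True
    family: str = "family"

    def __post_init__(self) -> None:
        if self.flank_total < 0:
            raise ValueError("flank_total must be non-negative")
        if self.max_per_family < 1:
            raise ValueError("max_per_family must be positive")
        if self.flank_source not in ("synthetic", "context"):
            raise ValueError(f"unknown flank source {self.flank_source!r}")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


def split_flanks(total: int, rng: np.random.Generator) -> tuple[int, int]:
    """Randomly split a flank budget between the 5' and 3' ends.

    The left share is uniform on ``0..total``; the two parts always sum to
    ``total``.
    """
    if total < 0:
        raise ValueError("flank total must be non-negative")
    left = int(rng.integers(0, total + 1))
    return left, total - left


def ambiguity_filter(seq: RnaSequence | str) -> bool:
    """Keep a sequence only when every residue is one of A, C, G, U."""
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    return set(residues.upper().replace("T", "U")) <= CANONICAL_BASES


def reverse_complement(rna: str) -> str:
    """Reverse complement over the RNA alphabet (A<->U, C<->G)."""
    return rna.upper().replace("T", "U").translate(_RC)[::-1]


def reverse_complement_filter(
    rows: Sequence[tuple[str, RnaSequence, SecondaryStructure]],
    contexts: dict[str, str] | None = None,
) -> list[tuple[str, RnaSequence, SecondaryStructure]]:
    """Drop rows whose motif occurs reverse-complemented in their context.

    When a row has no context sequence the motif itself is searched.  This
    is one defensible reading of removing motifs "appearing in the reverse
    complement"; it can be disabled entirely via the generator config.
    """
    surviving = []
    for row_id, seq, struct in rows:
        haystack = (contexts or {}).get(row_id, seq.residues)
        if reverse_complement(seq.residues) in haystack:
            continue
        surviving.append((row_id, seq, struct))
    return surviving


def _motif_rows(source) -> list[tuple[str, RnaSequence, SecondaryStructure]]:
    if isinstance(source, SeedAlignment):
        rows = []
        for idx in range(source.n_rows):
            seq, struct = project_consensus(source, idx)
            if len(seq) == 0:
                continue
            rows.append((source.rows[idx][0], seq, struct))
        return rows
    out = []
    for seq, struct in source:
        if isinstance(struct, str):
            struct = parse_dbn(struct)
        out.append((seq.identifier, seq, struct))
    return out


def _synthetic_flank(
    length: int, rng: np.random.Generator, composition
) -> str:
    if length == 0:
        return ""
    bases = np.array(list("ACGU"))
    return "".join(rng.choice(bases, size=length, p=list(composition)))


def _context_flanks(
    context: str, motif: str, left: int, right: int
) -> tuple[str, str] | None:
    at = context.find(motif)
    if at < 0:
        return None
    left_avail = context[:at]
    right_avail = context[at + len(motif):]
    return left_avail[-left:] if left else "", right_avail[:right]


def generate(
    source,
    cfg: GeneratorConfig = GeneratorConfig(),
    contexts: dict[str, str] | None = None,
) -> tuple[list[BenchmarkRecord], dict]:
    """Run the full benchmark-generation pipeline.

    ``source`` is a :class:`~rnamotifbench.formats.SeedAlignment` or an
    iterable of ``(RnaSequence, SecondaryStructure-or-dot-bracket)`` pairs.
    Optional ``contexts`` map row identifiers to sequences containing the
    motif; they serve both the reverse-complement filter and, with
    ``flank_source="context"``, the flanking sequence itself.

    Returns the records plus a manifest dictionary (config, seed and
    per-record truth) sufficient to reproduce and to score the benchmark.
    Raises :class:`EmptyBenchmarkError` when nothing survives.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = _motif_rows(source)
    if cfg.rc_filter:
        rows = reverse_complement_filter(rows, contexts)

    if len(rows) > cfg.max_per_family:
        idx = rng.choice(len(rows), size=cfg.max_per_family, replace=False)
        rows = [rows[int(k)] for k in idx]
    else:
        rng.shuffle(rows)

    records = []
    skipped: list[str] = []
    for k, (row_id, motif_seq, struct) in enumerate(rows, start=1):
        left, right = split_flanks(cfg.flank_total, rng)
        if cfg.flank_source == "context":
            ctx = (contexts or {}).get(row_id)
            flanks = (
                _context_flanks(ctx, motif_seq.residues, left, right)
                if ctx
                else None
            )
            if flanks is None:
                skipped.append(row_id)
                continue
            lseq, rseq = flanks
        else:
            lseq = _synthetic_flank(left, rng, cfg.base_composition)
            rseq = _synthetic_flank(right, rng, cfg.base_composition)
        full = lseq + motif_seq.residues + rseq
        if cfg.discard_ambiguous and not ambiguity_filter(full):
            skipped.append(row_id)
            continue
        ident = f"{cfg.family}_{k:03d}"
        records.append(
            BenchmarkRecord(
                identifier=ident,
                sequence=RnaSequence(ident, full),
                motif_start=len(lseq) + 1,
                motif_end=len(lseq) + len(motif_seq),
                structure=struct,
                source_row=row_id,
                family=cfg.family,
            )
        )
    if not records:
        raise EmptyBenchmarkError(
            "no sequences survived filtering; benchmark is empty"
        )
    manifest = _build_manifest(records, cfg, skipped)
    return records, manifest


def _build_manifest(
    records: list[BenchmarkRecord], cfg: GeneratorConfig, skipped: list[str]
) -> dict:
    rows = []
    for rec in records:
        tier = (
            "unclassified"
            if rec.structure.pseudoknotted
            else classify_tier(complexity_profile(rec.structure))
        )
        rows.append(
            {
                "id": rec.identifier,
                "family": rec.family,
                "tier": tier,
                "motif_start": rec.motif_start,
                "motif_end": rec.motif_end,
                "structure_dbn": rec.structure.to_dbn(),
                "source_row": rec.source_row,
                "seed": cfg.seed,
            }
        )
    return {
        "config": asdict(cfg),
        "n_records": len(records),
        "skipped_rows": skipped,
        "records": rows,
    }


MANIFEST_COLUMNS = [
    "id", "family", "tier", "motif_start", "motif_end",
    "structure_dbn", "source_row", "seed",
]


def write_benchmark(
    records: list[BenchmarkRecord], manifest: dict, out_dir: str | Path
) -> dict[str, Path]:
    """Write the benchmark FASTA plus TSV and JSON manifests.

    Returns the paths written, keyed by role.
    """
    if not records:
        raise EmptyBenchmarkError("refusing to write an empty benchmark")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "benchmark.fasta"
    write_fasta([rec.sequence for rec in records], fasta)
    tsv = out_dir / "manifest.tsv"
    pd.DataFrame(manifest["records"], columns=MANIFEST_COLUMNS).to_csv(
        tsv, sep="\t", index=False
    )
    js = out_dir / "manifest.json"
    js.write_text(json.dumps(manifest, indent=2) + "\n")
    return {"fasta": fasta, "manifest_tsv": tsv, "manifest_json": js}


def read_manifest(path: str | Path, fasta: str | Path | None = None):
    """Load a benchmark back from its JSON manifest (plus FASTA when given).

    Without the FASTA, full sequences are unavailable and records are
    returned as manifest rows; with it, full :class:`BenchmarkRecord`
    objects are rebuilt.
    """
    manifest = json.loads(Path(path).read_text())
    if fasta is None:
        return manifest, None
    from .formats import read_fasta

    seqs = {s.identifier: s for s in read_fasta(fasta)}
    records = []
    for row in manifest["records"]:
        seq = seqs[row["id"]]
        records.append(
            BenchmarkRecord(
                identifier=row["id"],
                sequence=seq,
                motif_start=int(row["motif_start"]),
                motif_end=int(row["motif_end"]),
                structure=parse_dbn(row["structure_dbn"]),
                source_row=row["source_row"],
                family=row["family"],
            )
        )
    return manifest, records
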