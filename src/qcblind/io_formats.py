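"""Strict readers and writers for the formats the pipeline touches.

All genomic intervals are 0-based half-open internally; the 1-based closed
GFF convention is converted at the file boundary only.  FASTQ is phred+33
only — phred+64 files are rejected rather than auto-detected, because a
silent mis-detection corrupts every downstream quality decision.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Malformed input file; message carries the file name and line number."""


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Reads


@dataclass
class ReadRecord:
    """A sequencing read with per-base phred qualities.

    ``mate`` is one of ``single``, ``mate1``, ``mate2``; the two mates of a
    pair share ``pair_id``.
    """

    read_id: str
    sequence: str
    qualities: np.ndarray  # uint8 phred scores, same length as sequence
    mate: str = "single"
    pair_id: str = ""

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if not self.pair_id:
            self.pair_id = self.read_id

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """An ordered collection of reads; mates of a pair are adjacent."""

    reads: list[ReadRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[ReadRecord]:
        return iter(self.reads)

    def __getitem__(self, i):
        return self.reads[i]

    @property
    def n_pairs(self) -> int:
        return sum(1 for r in self.reads if r.mate == "mate1")

    def pairs(self) -> Iterator[tuple[ReadRecord, ReadRecord]]:
        """Yield (mate1, mate2) tuples; requires interleaved pairing."""
        it = iter(self.reads)
        for r in it:
            if r.mate == "mate1":
                m2 = next(it, None)
                if m2 is None or m2.mate != "mate2" or m2.pair_id != r.pair_id:
                    raise ValueError(f"pair {r.pair_id}: mates not interleaved")
                yield r, m2

    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)


def _parse_fastq_stream(handle, path: str) -> Iterator[tuple[str, str, np.ndarray, int]]:
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ParseError(f"{path}:{lineno}: expected '@' header, got {header[:30]!r}")
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        if not seq or not plus or not qual:
            raise ParseError(
                f"{path}:{lineno}: truncated FASTQ record (starts here)"
            )
        lineno += 3
        seq = seq.rstrip("\n")
        qual = qual.rstrip("\n")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}:{lineno}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
        if q.size and q.min() < 33:
            raise ParseError(f"{path}:{lineno}: quality character below '!'; not phred+33")
        yield header[1:].split()[0], seq, (q - 33).astype(np.uint8), lineno


def _strip_mate_suffix(read_id: str) -> str:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def read_fastq(path, paired_path=None) -> ReadSet:
    """Read single or paired FASTQ (phred+33, optionally gzipped).

    With ``paired_path``, records are interleaved mate1/mate2 in file order
    and mates share a ``pair_id`` (the read id with any ``/1``/``/2`` suffix
    stripped).
    """
    path = os.fspath(path)
    with _open_text(path) as fh:
        records = list(_parse_fastq_stream(fh, path))
    if paired_path is None:
        return ReadSet([ReadRecord(rid, seq, q, "single", rid) for rid, seq, q, _ in records])
    paired_path = os.fspath(paired_path)
    with _open_text(paired_path) as fh:
        records2 = list(_parse_fastq_stream(fh, paired_path))
    if len(records) != len(records2):
        raise ParseError(
            f"{paired_path}: {len(records2)} records but {path} has {len(records)}"
        )
    reads: list[ReadRecord] = []
    for (id1, s1, q1, ln1), (id2, s2, q2, _) in zip(records, records2):
        pid = _strip_mate_suffix(id1)
        if _strip_mate_suffix(id2) != pid:
            raise ParseError(f"{path}:{ln1}: mate ids {id1!r}/{id2!r} do not pair")
        reads.append(ReadRecord(id1, s1, q1, "mate1", pid))
        reads.append(ReadRecord(id2, s2, q2, "mate2", pid))
    return ReadSet(reads)


def write_fastq(reads: ReadSet | Iterable[ReadRecord], path, paired_path=None) -> None:
    """Write reads as FASTQ; with ``paired_path``, mate1s go to ``path`` and
    mate2s to ``paired_path``."""
    reads = list(reads)
    if paired_path is None:
        with _open_text(path, "wt") as fh:
            for r in reads:
                _write_fastq_record(fh, r)
        return
    with _open_text(path, "wt") as f1, _open_text(paired_path, "wt") as f2:
        for r in reads:
            _write_fastq_record(f2 if r.mate == "mate2" else f1, r)


def _write_fastq_record(fh, r: ReadRecord) -> None:
    qual = (np.asarray(r.qualities, dtype=np.uint8) + 33).tobytes().decode("ascii")
    fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``[(id, sequence), ...]`` (uppercased)."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Gene annotations


@dataclass
class GenomeAnnotation:
    """Gene intervals on one genome, 0-based half-open.

    ``genes`` holds ``(gene_id, start, end, strand)`` tuples with
    ``0 <= start < end`` and unique gene ids.
    """

    genome_id: str
    genes: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for gid, start, end, strand in self.genes:
            if not (0 <= start < end):
                raise ValueError(f"gene {gid}: bad interval [{start}, {end})")
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid}")
            seen.add(gid)

    def __len__(self) -> int:
        return len(self.genes)


def read_gff_genes(path, dialect: str | None = None,
                   feature_types: Sequence[str] = ("gene",)) -> GenomeAnnotation:
    """Read gene intervals from GFF3 (1-based closed) or BED (0-based half-open).

    The dialect is taken from the extension (.gff/.gff3 vs .bed) unless given
    explicitly; anything else is an error rather than a guess.
    """
    path = os.fspath(path)
    if dialect is None:
        stem = path[: -len(".gz")] if path.endswith(".gz") else path
        ext = Path(stem).suffix.lower()
        if ext in (".gff", ".gff3"):
            dialect = "gff"
        elif ext == ".bed":
            dialect = "bed"
        else:
            raise ParseError(f"{path}: cannot infer coordinate dialect from extension {ext!r}")
    if dialect not in ("gff", "bed"):
        raise ParseError(f"{path}: unknown coordinate dialect {dialect!r}")

    genes: list[tuple[str, int, int, str]] = []
    genome_id = ""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if dialect == "gff":
                    if len(cols) < 8:
                        raise ValueError("fewer than 8 columns")
                    if cols[2] not in feature_types:
                        continue
                    start1, end1 = int(cols[3]), int(cols[4])
                    start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
                    strand = cols[6] if cols[6] in "+-" else "+"
                    gid = _gff_attr_id(cols[8] if len(cols) > 8 else "", lineno)
                else:
                    if len(cols) < 3:
                        raise ValueError("fewer than 3 columns")
                    start, end = int(cols[1]), int(cols[2])
                    strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
                    gid = cols[3] if len(cols) > 3 and cols[3] else f"feature_{lineno}"
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end {end} <= start {start}")
            genome_id = genome_id or cols[0]
            genes.append((gid, start, end, strand))
    return GenomeAnnotation(genome_id=genome_id, genes=genes)


def _gff_attr_id(attrs: str, lineno: int) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
    )
    return fields.get("ID") or fields.get("Name") or f"feature_{lineno}"


def write_gff_genes(annotation: GenomeAnnotation, path) -> None:
    """Write gene intervals as GFF3 (internal 0-based half-open -> 1-based closed)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for gid, start, end, strand in annotation.genes:
            fh.write(
                f"{annotation.genome_id}\tqcblind\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gid}\n"
            )


def write_bed(annotation: GenomeAnnotation, path) -> None:
    with _open_text(path, "wt") as fh:
        for gid, start, end, strand in annotation.genes:
            fh.write(f"{annotation.genome_id}\t{start}\t{end}\t{gid}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class TruthTable:
    """read_id -> source species, and species -> role ({target, contaminant})."""

    assignments: dict[str, str]
    roles: dict[str, str]

    def __post_init__(self):
        bad = set(self.roles.values()) - {"target", "contaminant"}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def target_species(self) -> list[str]:
        return sorted(s for s, r in self.roles.items() if r == "target")

    def is_target_read(self, read_id: str) -> bool:
        sp = self.assignments.get(read_id)
        return sp is not None and self.roles.get(sp) == "target"

    def species_of(self, read_id: str) -> str | None:
        return self.assignments.get(read_id)


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"read_id", "species_id", "role"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: truth table needs columns {sorted(need)}")
    roles = dict(zip(df["species_id"], df["role"]))
    return TruthTable(dict(zip(df["read_id"], df["species_id"])), roles)


def write_truth(truth: TruthTable, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("read_id\tspecies_id\trole\n")
        for rid, sp in truth.assignments.items():
            fh.write(f"{rid}\t{sp}\t{truth.roles[sp]}\n")


# ---------------------------------------------------------------------------
# Report tables

_PCT_SUFFIX = ("_pct", "_loss")


def write_tables(report, out_dir) -> list[str]:
    """Write an evaluation report as a bundle of TSVs plus a JSON summary.

    ``report`` must provide ``to_frames() -> dict[str, DataFrame]`` and
    ``summary() -> dict``.  Percentage columns (``*_pct``) are written with
    one decimal; full precision lives in ``summary.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in report.to_frames().items():
        frame = frame.copy()
        for col in frame.columns:
            if str(col).endswith(_PCT_SUFFIX):
                frame[col] = frame[col].astype(float).round(1)
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.1f")
        written.append(str(path))
    spath = out_dir / "summary.json"
    with open(spath, "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(str(spath))
    return written


def read_tables(out_dir) -> dict[str, pd.DataFrame]:
    """Read back a :func:`write_tables` bundle (TSVs only)."""
    out_dir = Path(out_dir)
    return {
        p.stem: pd.read_csv(p, sep="\t")
        for p in sorted(out_dir.glob("*.tsv"))
    }
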