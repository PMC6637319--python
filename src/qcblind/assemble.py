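"""Minimal de Bruijn assembler and contig preparation for binning.

The assembler targets low-error reads: canonical k-mers (k odd, default 31)
are counted over all reads, k-mers seen fewer than ``min_count`` times are
dropped (purging singleton error k-mers), and maximal non-branching paths of
the remaining bidirected graph are emitted as unitigs.  Contig preparation
then applies the binning length window: contigs shorter than ``min_len`` are
removed and longer ones are cut into ``max_len`` pieces, with an undersized
tail merged back into the previous piece so no bases are lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._kmers import (canonical_window_codes, decode_kmer, encode, revcomp,
                     revcomp_code)
from .io_formats import ReadSet


@dataclass
class ContigRecord:
    """An assembled (or externally supplied) contig.

    ``source_contig`` names the pre-fragmentation parent; it equals
    ``contig_id`` for unfragmented contigs.
    """

    contig_id: str
    sequence: str
    origin: str = "builtin"  # {builtin, external}
    source_contig: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.contig_id}: empty sequence")
        if not self.source_contig:
            self.source_contig = self.contig_id

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContigSet:
    contigs: list[ContigRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids")

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[ContigRecord]:
        return iter(self.contigs)

    def __getitem__(self, i):
        return self.contigs[i]

    def by_id(self) -> dict[str, ContigRecord]:
        return {c.contig_id: c for c in self.contigs}

    def total_bases(self) -> int:
        return sum(len(c) for c in self.contigs)

    def to_fasta_records(self) -> list[tuple[str, str]]:
        return [(c.contig_id, c.sequence) for c in self.contigs]


@dataclass
class AssemblyStats:
    n_contigs: int
    n50: int
    mean_length: float
    total_bases: int


# ---------------------------------------------------------------------------
# k-mer counting and unitig extraction


def count_canonical_kmers(reads: Iterable, k: int,
                          chunk_bases: int = 8_000_000) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes and counts over a read set (N-containing k-mers
    skipped).  Reads are concatenated with separators and encoded in chunks
    so the whole count is a handful of vectorized passes."""
    parts: list[np.ndarray] = []
    buf: list[str] = []
    size = 0

    def flush():
        nonlocal buf, size
        if buf:
            codes, valid = canonical_window_codes(encode("N".join(buf)), k)
            parts.append(codes[valid])
            buf, size = [], 0

    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else r
        buf.append(seq)
        size += len(seq) + 1
        if size >= chunk_bases:
            flush()
    flush()
    if not parts:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    return np.unique(np.concatenate(parts), return_counts=True)


def build_unitigs(reads: ReadSet, k: int = 31, min_count: int = 2) -> ContigSet:
    """Assemble maximal non-branching de Bruijn paths into contigs.

    Requires odd ``k`` (no self-reverse-complement k-mers) shorter than the
    reads.  Emitted contigs are in canonical orientation (lexicographic min
    of the two strands) and the output order is deterministic.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    codes, counts = count_canonical_kmers(reads, k)
    keep = codes[counts >= min_count]
    if keep.size == 0:
        warnings.warn("no k-mer passed the abundance filter; empty assembly")
        return ContigSet([])
    from ._kmers import revcomp_codes

    keep_rc = revcomp_codes(keep, k)
    # membership set holds both orientations so walking needs no rc calls
    oriented = set(keep.tolist())
    oriented.update(keep_rc.tolist())

    mask = (1 << (2 * k)) - 1
    high_shift = 2 * (k - 1)

    def succs(c: int) -> list[int]:
        base = (c << 2) & mask
        return [base | b for b in range(4) if base | b in oriented]

    def preds(c: int) -> list[int]:
        high = c >> 2
        return [(b << high_shift) | high for b in range(4)
                if (b << high_shift) | high in oriented]

    def walk(start: int, start_rc: int, visited: set[int]) -> list[int]:
        bases = []
        cur = start
        while True:
            nxt_list = succs(cur)
            if len(nxt_list) != 1:
                break
            nxt = nxt_list[0]
            if len(preds(nxt)) != 1:
                break
            if nxt == start or nxt == start_rc or nxt in visited:
                break
            visited.add(nxt)
            visited.add(revcomp_code(nxt, k))
            bases.append(nxt & 3)
            cur = nxt
        return bases

    visited: set[int] = set()
    unitigs: list[str] = []
    for c in sorted(keep.tolist()):
        if c in visited:
            continue
        rc_c = revcomp_code(c, k)
        visited.add(c)
        visited.add(rc_c)
        fwd = walk(c, rc_c, visited)
        bwd = walk(rc_c, c, visited)
        left = revcomp("".join("ACGT"[b] for b in bwd))
        seq = left + decode_kmer(c, k) + "".join("ACGT"[b] for b in fwd)
        rc = revcomp(seq)
        unitigs.append(min(seq, rc))

    contigs = [
        ContigRecord(f"u{i + 1:06d}", seq)
        for i, seq in enumerate(unitigs)
        if len(seq) >= k
    ]
    return ContigSet(contigs)


def external_contigs(records: list[tuple[str, str]]) -> ContigSet:
    """Wrap contigs from an external assembler (FASTA records)."""
    return ContigSet([
        ContigRecord(cid, seq.upper(), origin="external") for cid, seq in records
    ])


# ---------------------------------------------------------------------------
# Contig preparation


def fragmentation_plan(length: int, min_len: int = 1000,
                       max_len: int = 10000) -> list[tuple[int, int]] | None:
    """Piece boundaries the length window assigns to a contig of ``length``.

    Returns ``None`` for contigs below ``min_len`` (dropped); otherwise a
    list of half-open intervals.  Contigs above ``max_len`` are cut into
    consecutive ``max_len`` pieces with an undersized tail merged back into
    the previous piece (which may then exceed ``max_len``).
    """
    if length < min_len:
        return None
    if length <= max_len:
        return [(0, length)]
    bounds = list(range(0, length, max_len)) + [length]
    if bounds[-1] - bounds[-2] < min_len and len(bounds) > 2:
        del bounds[-2]  # merge undersized tail into the previous piece
    return list(zip(bounds[:-1], bounds[1:]))


def prepare_contigs(contigs: ContigSet, min_len: int = 1000,
                    max_len: int = 10000) -> ContigSet:
    """Apply the binning length window (drop short, cut long).

    Total bases of surviving inputs are conserved; pieces of a fragmented
    contig are named ``<id>:<n>`` and record their parent in
    ``source_contig``.
    """
    out: list[ContigRecord] = []
    for c in contigs:
        plan = fragmentation_plan(len(c), min_len, max_len)
        if plan is None:
            continue
        if len(plan) == 1:
            out.append(ContigRecord(c.contig_id, c.sequence, c.origin, c.source_contig))
            continue
        for i, (s, e) in enumerate(plan):
            out.append(ContigRecord(f"{c.contig_id}:{i + 1}", c.sequence[s:e],
                                    c.origin, c.contig_id))
    return ContigSet(out)


def project_alignments(alignments: pd.DataFrame, contigs: ContigSet,
                       min_len: int = 1000, max_len: int = 10000) -> pd.DataFrame:
    """Re-express read alignments on unprepared contigs as alignments on the
    prepared pieces of the same length window.

    A read survives when its aligned interval falls entirely inside one
    piece; reads on dropped contigs or straddling a cut are removed.  For
    unambiguously mapping reads this equals re-mapping against the prepared
    set directly, at a fraction of the cost.
    """
    plans = {c.contig_id: fragmentation_plan(len(c), min_len, max_len)
             for c in contigs}
    parts: list[pd.DataFrame] = []
    for cid, grp in alignments.groupby("contig_id", sort=False):
        plan = plans.get(cid)
        if plan is None:
            continue
        if len(plan) == 1:
            parts.append(grp)
            continue
        starts = np.array([s for s, _ in plan])
        ends = np.array([e for _, e in plan])
        idx = np.searchsorted(starts, grp["start"].to_numpy(), side="right") - 1
        ok = grp["end"].to_numpy() <= ends[idx]  # drop straddlers
        g = grp.loc[ok].copy()
        gi = idx[ok]
        g["contig_id"] = [f"{cid}:{i + 1}" for i in gi]
        g["start"] = g["start"].to_numpy() - starts[gi]
        g["end"] = g["end"].to_numpy() - starts[gi]
        parts.append(g)
    if not parts:
        return alignments.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Coverage and stats


def compute_coverage(contigs: ContigSet, reads: ReadSet | None = None,
                     alignments: pd.DataFrame | None = None,
                     sample: str = "s1",
                     min_identity: float = 0.95) -> pd.DataFrame:
    """Mean per-base read depth per contig for one sample.

    Either a read set (mapped with the built-in mapper) or a precomputed
    alignment table (columns contig_id/start/end) may be supplied.  Returns
    a tidy frame (contig_id, sample, mean_depth) covering every contig.
    """
    if alignments is None:
        if reads is None:
            raise ValueError("need reads or alignments")
        from .target_id import map_reads

        alignments = map_reads(reads, contigs, min_identity=min_identity)
    lengths = {c.contig_id: len(c) for c in contigs}
    depth = {cid: 0.0 for cid in lengths}
    if len(alignments):
        span = (alignments["end"] - alignments["start"]).groupby(
            alignments["contig_id"]
        ).sum()
        for cid, total in span.items():
            if cid in depth:
                depth[cid] = float(total) / lengths[cid]
    return pd.DataFrame({
        "contig_id": list(depth.keys()),
        "sample": sample,
        "mean_depth": list(depth.values()),
    })


def assembly_stats(contigs: ContigSet) -> AssemblyStats:
    """Contig count, N50, mean length and total bases.

    N50 is the length of the contig at which the cumulative length, in
    descending length order, first reaches half of the total bases.
    """
    if len(contigs) == 0:
        raise ValueError("assembly_stats of an empty contig set")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for ln in lengths:
        acc += ln
        if acc * 2 >= total:
            n50 = ln
            break
    return AssemblyStats(
        n_contigs=len(lengths),
        n50=n50,
        mean_length=total / len(lengths),
        total_bases=total,
    )
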