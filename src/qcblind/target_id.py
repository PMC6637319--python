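"""Marker-gene target calling and read rescue.

Marker genes of the target species are aligned to the binned contigs with
the built-in seed-and-extend aligner (an external tabular hits file can be
dropped in instead); any cluster with at least ``min_markers`` distinct
markers hitting its contigs is called a target cluster, every contig of
those clusters becomes a target contig, and raw reads are rescued by
mapping them onto the contigs and keeping pairs whose best alignment lands
on a target contig.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._align import SeedIndex, evalue, seed_extend_search
from ._kmers import revcomp
from .assemble import ContigSet
from .binning import ClusterAssignment
from .io_formats import ReadRecord, ReadSet


@dataclass
class MarkerGene:
    marker_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 100:
            raise ValueError(f"marker {self.marker_id} shorter than 100 bp")


@dataclass
class MarkerHit:
    marker_id: str
    contig_id: str
    length: int
    identity: float
    score: float
    evalue: float


@dataclass
class TargetCall:
    """Marker-identified target clusters, their contigs, and rescued reads."""

    target_clusters: list[int] = field(default_factory=list)
    target_contigs: list[str] = field(default_factory=list)
    rescued_read_ids: list[str] = field(default_factory=list)
    marker_tally: dict[int, list[str]] = field(default_factory=dict)
    no_target: bool = False


# ---------------------------------------------------------------------------
# Marker alignment


def align_markers(markers: list[MarkerGene], contigs: ContigSet,
                  evalue_cutoff: float = 1e-20,
                  seed_len: int = 15, match: int = 1, mismatch: int = -2,
                  xdrop: int = 20,
                  min_identity: float = 0.0,
                  min_length: int = 0) -> list[MarkerHit]:
    """Local-align markers against contigs and keep significant hits.

    Significance uses the documented Karlin-Altschul form
    ``E = K * m * n * exp(-lambda * S)`` with n the total contig bases (see
    :mod:`qcblind._align`).  Optional identity/length floors are off by
    default; the e-value cutoff alone gates hits.
    """
    if not markers:
        raise ValueError("no marker genes supplied")
    ids = [m.marker_id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids")
    if len(contigs) == 0:
        warnings.warn("empty contig set: no marker hits possible")
        return []
    index = SeedIndex(contigs.to_fasta_records(), seed_len)
    raw = seed_extend_search([(m.marker_id, m.sequence) for m in markers],
                             index, step=1, match=match, mismatch=mismatch,
                             xdrop=xdrop)
    mlen = {m.marker_id: len(m.sequence) for m in markers}
    hits = []
    for h in raw:
        e = evalue(h.score, mlen[h.query_id], index.total_bases, match, mismatch)
        if e > evalue_cutoff:
            continue
        if h.identity < min_identity or h.length < min_length:
            continue
        hits.append(MarkerHit(h.query_id, h.subject_id, h.length,
                              h.identity, float(h.score), e))
    return hits


def read_tabular_hits(path, evalue_cutoff: float = 1e-20) -> list[MarkerHit]:
    """Parse a 12-column tabular hits file (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore) and filter it
    at the same e-value cutoff the built-in aligner uses."""
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        if row.evalue > evalue_cutoff:
            continue
        hits.append(MarkerHit(str(row.qseqid), str(row.sseqid), int(row.length),
                              float(row.pident) / 100.0, float(row.bitscore),
                              float(row.evalue)))
    return hits


def read_sam_alignments(path, min_identity: float = 0.95) -> pd.DataFrame:
    """Read a SAM file of read-vs-contig alignments as a drop-in replacement
    for the built-in mapper's table.

    Primary alignments only; identity is derived from the NM tag (edit
    distance) over the aligned length and filtered at ``min_identity``.
    Returns the same columns as :func:`map_reads`.
    """
    import pysam

    rows = {k: [] for k in ("read_id", "contig_id", "start", "end",
                            "strand", "identity")}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            length = rec.query_alignment_length
            if not length:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            identity = 1.0 - nm / length
            if identity < min_identity:
                continue
            name = rec.query_name
            if rec.is_paired and name and not name.endswith(("/1", "/2")):
                name = f"{name}/{2 if rec.is_read2 else 1}"
            rows["read_id"].append(name)
            rows["contig_id"].append(rec.reference_name)
            rows["start"].append(rec.reference_start)
            rows["end"].append(rec.reference_end)
            rows["strand"].append("-" if rec.is_reverse else "+")
            rows["identity"].append(identity)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Target-cluster calling


def call_target_clusters(hits: list[MarkerHit], assignment: ClusterAssignment,
                         min_markers: int = 1) -> TargetCall:
    """Call every cluster hit by >= ``min_markers`` distinct markers.

    Zero qualifying clusters yields an explicit no-target result (the
    pipeline halts cleanly) rather than an exception.
    """
    tally: dict[int, set[str]] = {}
    for h in hits:
        if h.contig_id not in assignment.labels:
            continue
        tally.setdefault(assignment.labels[h.contig_id], set()).add(h.marker_id)
    clusters = sorted(c for c, mk in tally.items() if len(mk) >= min_markers)
    if not clusters:
        return TargetCall(no_target=True)
    contigs = sorted(
        cid for cid, c in assignment.labels.items() if c in set(clusters)
    )
    return TargetCall(
        target_clusters=clusters,
        target_contigs=contigs,
        marker_tally={c: sorted(tally[c]) for c in clusters},
    )


# ---------------------------------------------------------------------------
# Read mapping (built-in, exact-seed end-to-end)


class _ContigSeedTable:
    """Sorted-array seed table over the concatenated contig sequences; seed
    lookups happen in bulk via searchsorted rather than per-seed dict gets."""

    def __init__(self, contigs: ContigSet, seed_len: int):
        import numpy as np

        from ._kmers import encode, window_codes

        self.seed_len = seed_len
        self.ids = [c.contig_id for c in contigs]
        self.seqs = [c.sequence for c in contigs]
        self.lens = [len(s) for s in self.seqs]
        big = "N".join(self.seqs)  # separators invalidate boundary windows
        if len(big) < seed_len:
            self.codes = np.empty(0, np.uint64)
            self.gpos = np.empty(0, np.int64)
            self.contig_idx = np.empty(0, np.int64)
            self.local_pos = np.empty(0, np.int64)
            return
        codes, valid = window_codes(encode(big), seed_len)
        gpos = np.flatnonzero(valid)
        codes = codes[gpos]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        gpos = gpos[order]
        starts = np.cumsum([0] + [len(s) + 1 for s in self.seqs])
        ci = np.searchsorted(starts, gpos, side="right") - 1
        self.contig_idx = ci.astype(np.int64)
        self.local_pos = (gpos - starts[ci]).astype(np.int64)


def map_reads(reads: ReadSet, contigs: ContigSet,
              min_identity: float = 0.95, seed_len: int = 21,
              batch_size: int = 100_000) -> pd.DataFrame:
    """Assign each read to the contig giving its best end-to-end alignment.

    Candidate placements come from exact ``seed_len``-mer seeds at three read
    offsets on both strands; a candidate counts when the whole read fits
    inside the contig at >= ``min_identity``.  Ties at equal identity go to
    the lowest contig id.  Returns a frame (read_id, contig_id, start, end,
    strand, identity) with one row per aligned read.
    """
    import numpy as np

    from ._kmers import encode, revcomp_codes, window_codes

    table = _ContigSeedTable(contigs, seed_len)
    rows_id, rows_cid, rows_start, rows_end, rows_strand, rows_ident = (
        [], [], [], [], [], []
    )
    if table.codes.size == 0:
        return _alignment_frame(rows_id, rows_cid, rows_start, rows_end,
                                rows_strand, rows_ident)
    exact_only = min_identity >= 1.0
    all_reads = list(reads)
    for b0 in range(0, len(all_reads), batch_size):
        batch = [r for r in all_reads[b0 : b0 + batch_size]
                 if len(r.sequence) >= seed_len]
        if not batch:
            continue
        L = np.array([len(r.sequence) for r in batch], dtype=np.int64)
        rstart = np.concatenate(([0], np.cumsum(L + 1)[:-1]))
        rcodes, rvalid = window_codes(encode("N".join(r.sequence for r in batch)),
                                      seed_len)
        offs = np.stack([np.zeros_like(L), (L - seed_len) // 2, L - seed_len], 1)
        fpos = rstart[:, None] + offs
        fwd_codes = rcodes[fpos]
        fwd_ok = rvalid[fpos]
        rpos = rstart[:, None] + (L[:, None] - seed_len - offs)
        rc_codes = revcomp_codes(rcodes[rpos], seed_len)
        rc_ok = rvalid[rpos]
        seed_codes = np.concatenate([fwd_codes, rc_codes], axis=1)
        seed_ok = np.concatenate([fwd_ok, rc_ok], axis=1)
        lo = np.searchsorted(table.codes, seed_codes, side="left")
        hi = np.searchsorted(table.codes, seed_codes, side="right")

        n_off = offs.shape[1]
        offs_l = offs.tolist()
        lo_l, hi_l, ok_l = lo.tolist(), hi.tolist(), seed_ok.tolist()
        cidx, lpos = table.contig_idx, table.local_pos
        ids, seqs, lens = table.ids, table.seqs, table.lens
        for ri, r in enumerate(batch):
            rl = int(L[ri])
            best = None  # (identity, contig_id, ci, start, strand)
            for slot in range(2 * n_off):
                if not ok_l[ri][slot]:
                    continue
                strand = "+" if slot < n_off else "-"
                off = offs_l[ri][slot % n_off]
                seq = r.sequence if strand == "+" else revcomp(r.sequence)
                for t in range(lo_l[ri][slot], hi_l[ri][slot]):
                    ci = int(cidx[t])
                    start = int(lpos[t]) - off
                    if start < 0 or start + rl > lens[ci]:
                        continue
                    window = seqs[ci][start : start + rl]
                    if window == seq:
                        ident = 1.0
                    elif exact_only:
                        continue
                    else:
                        mism = sum(a != b for a, b in zip(window, seq))
                        ident = 1.0 - mism / rl
                        if ident < min_identity:
                            continue
                    if best is None or ident > best[0] or (
                        ident == best[0] and ids[ci] < best[1]
                    ):
                        best = (ident, ids[ci], ci, start, strand)
                if best is not None and best[0] == 1.0:
                    # perfect hit: equal-identity ties share this seed range,
                    # so the lowest-contig-id rule has already been applied
                    break
            if best is not None:
                ident, cid, ci, start, strand = best
                rows_id.append(r.read_id)
                rows_cid.append(cid)
                rows_start.append(start)
                rows_end.append(start + rl)
                rows_strand.append(strand)
                rows_ident.append(ident)
    return _alignment_frame(rows_id, rows_cid, rows_start, rows_end,
                            rows_strand, rows_ident)


def _alignment_frame(ids, cids, starts, ends, strands, idents) -> pd.DataFrame:
    return pd.DataFrame({
        "read_id": ids,
        "contig_id": cids,
        "start": starts,
        "end": ends,
        "strand": strands,
        "identity": idents,
    })


# ---------------------------------------------------------------------------
# Read rescue


def rescue_reads(alignments: pd.DataFrame, call: TargetCall,
                 reads: ReadSet) -> tuple[TargetCall, ReadSet]:
    """Complete a target call with rescued reads.

    A pair is rescued when either mate's best alignment lands on a target
    contig; both mates are then emitted (mate rescue preserves genomic
    information).  Single reads are rescued on their own alignment.
    """
    if call.no_target:
        return call, ReadSet([])
    target_contigs = set(call.target_contigs)
    on_target = set(
        alignments.loc[alignments["contig_id"].isin(target_contigs), "read_id"]
    )
    rescued: list[ReadRecord] = []
    it = iter(reads)
    for r in it:
        if r.mate == "mate1":
            m2 = next(it)
            if r.read_id in on_target or m2.read_id in on_target:
                rescued.extend((r, m2))
        elif r.mate == "single":
            if r.read_id in on_target:
                rescued.append(r)
    call.rescued_read_ids = [r.read_id for r in rescued]
    return call, ReadSet(rescued)
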