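"""Synthetic contaminated-community simulator with ground truth.

The simulator emulates a single-target screening experiment: one target
genome mixed with several contaminant genomes at a chosen read proportion,
error-free (or uniformly substituted) paired 120 bp reads drawn from
constant-length fragments.  Marker genes, gene annotations and 16S-like
sequences are planted so that every downstream stage has a recoverable
ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._kmers import canonical_window_codes, encode, revcomp
from .io_formats import GenomeAnnotation, ReadRecord, ReadSet, TruthTable

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSpec:
    """One genome in a simulated community."""

    species_id: str
    sequence: str
    role: str = "contaminant"  # {target, contaminant}
    read_proportion: float = 0.0

    def __post_init__(self):
        if self.role not in ("target", "contaminant"):
            raise ValueError(f"role must be target/contaminant, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimConfig:
    """Read-simulation parameters.

    ``coverage`` is the fold coverage of the combined genome pool: the total
    number of read pairs is ``round(coverage * sum(genome lengths) /
    (2 * read_length))``; each genome's realized depth is then its read
    proportion times the pool's sequenced bases over its own length.
    """

    read_length: int = 120
    fragment_length: int = 200
    coverage: float = 100.0
    error_rate: float = 0.0
    seed: int = 0
    tiled: bool = False  # deterministic every-fragment_length tiling

    def __post_init__(self):
        if self.read_length > self.fragment_length:
            raise ValueError("read_length must be <= fragment_length")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


def make_random_genome(length: int, gc: float, seed: int,
                       species_id: str = "genome",
                       role: str = "contaminant") -> GenomeSpec:
    """I.i.d. random genome with the requested GC fraction.

    Lengths below 1000 bp are refused: they cannot be fragmented and binned.
    """
    if length < 1000:
        raise ValueError(f"genome length {length} < 1000 bp is too short to fragment")
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc must be strictly inside (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return GenomeSpec(species_id=species_id, sequence=seq, role=role)


def random_sequence(length: int, seed: int, gc: float = 0.5) -> str:
    """Plain random DNA string (marker genes, rRNA-like inserts)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def plant_marker_genes(genome: GenomeSpec, markers: list[tuple[str, str]],
                       seed: int) -> tuple[GenomeSpec, GenomeAnnotation]:
    """Insert marker sequences verbatim at random non-overlapping positions.

    Returns the grown genome plus an annotation of the planted sites (on the
    final coordinate system).  Insertion points are distinct, so planted
    copies never overlap each other.
    """
    if not markers:
        return genome, GenomeAnnotation(genome.species_id, [])
    L = len(genome.sequence)
    if len(markers) > L + 1:
        raise ValueError("not enough room to plant markers without overlap")
    rng = np.random.default_rng(seed)
    points = np.sort(rng.choice(L + 1, size=len(markers), replace=False))
    order = rng.permutation(len(markers))
    parts: list[str] = []
    sites: list[tuple[str, int, int, str]] = []
    prev = 0
    shift = 0
    for point, mi in zip(points, order):
        mid, mseq = markers[mi]
        parts.append(genome.sequence[prev:point])
        start = point + shift
        parts.append(mseq)
        sites.append((mid, start, start + len(mseq), "+"))
        shift += len(mseq)
        prev = point
    parts.append(genome.sequence[prev:])
    grown = dataclasses.replace(genome, sequence="".join(parts))
    sites.sort(key=lambda s: s[1])
    return grown, GenomeAnnotation(genome.species_id, sites)


def annotate_random_genes(genome: GenomeSpec, n_genes: int, gene_length: int,
                          seed: int) -> GenomeAnnotation:
    """Choose ``n_genes`` non-overlapping gene intervals on a genome.

    Starts are drawn by the classic spacing trick: sample sorted starts in a
    shrunken coordinate space, then re-inflate by one gene length per gene.
    """
    L = len(genome.sequence)
    if n_genes * gene_length > L:
        raise ValueError("genes do not fit in the genome without overlap")
    rng = np.random.default_rng(seed)
    slack = L - n_genes * gene_length
    offsets = np.sort(rng.choice(slack + 1, size=n_genes, replace=False if slack + 1 >= n_genes else True))
    genes = []
    for i, off in enumerate(offsets):
        start = int(off) + i * gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((f"gene_{i + 1:03d}", start, start + gene_length, strand))
    return GenomeAnnotation(genome.species_id, genes)


def expected_pair_count(genomes: list[GenomeSpec], config: SimConfig) -> int:
    """N = coverage * (total genome pool length) / (2 * read_length)."""
    pool = sum(len(g.sequence) for g in genomes)
    return int(round(config.coverage * pool / (2 * config.read_length)))


def simulate_reads(genomes: list[GenomeSpec],
                   config: SimConfig) -> tuple[ReadSet, TruthTable]:
    """Draw paired reads from a community and record per-read ground truth.

    Each pair picks its genome with probability ``read_proportion``, a
    constant-length fragment uniformly on that genome (or on a deterministic
    tiling when ``config.tiled``); mate1 is the fragment's 5' end and mate2
    the reverse complement of its 3' end.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    props = np.array([g.read_proportion for g in genomes], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"read proportions sum to {props.sum()}, not 1")
    if sum(g.role == "target" for g in genomes) != 1:
        raise ValueError("exactly one genome must have role=target")
    frag = config.fragment_length
    for g in genomes:
        if frag > len(g.sequence):
            raise ValueError(f"fragment ({frag} bp) longer than genome {g.species_id}")

    rng = np.random.default_rng(config.seed)
    n_pairs = expected_pair_count(genomes, config)
    counts = rng.multinomial(n_pairs, props)
    gidx = np.repeat(np.arange(len(genomes)), counts)
    rng.shuffle(gidx)

    starts_per_genome = []
    for g, c in zip(genomes, counts):
        hi = len(g.sequence) - frag + 1
        if config.tiled:
            tiling = np.arange(0, hi, frag)
            starts_per_genome.append(np.resize(tiling, c))
        else:
            starts_per_genome.append(rng.integers(0, hi, size=c))
    cursors = [0] * len(genomes)

    rl = config.read_length
    qual = np.full(rl, 40, dtype=np.uint8)  # shared; never mutated downstream
    reads: list[ReadRecord] = []
    assignments: dict[str, str] = {}
    for j, gi in enumerate(gidx):
        g = genomes[gi]
        s = int(starts_per_genome[gi][cursors[gi]])
        cursors[gi] += 1
        fragment = g.sequence[s : s + frag]
        seq1 = fragment[:rl]
        seq2 = revcomp(fragment[-rl:])
        if config.error_rate > 0:
            seq1 = _mutate(seq1, config.error_rate, rng)
            seq2 = _mutate(seq2, config.error_rate, rng)
        pid = f"r{j:07d}"
        reads.append(ReadRecord(pid + "/1", seq1, qual, "mate1", pid))
        reads.append(ReadRecord(pid + "/2", seq2, qual, "mate2", pid))
        assignments[pid + "/1"] = g.species_id
        assignments[pid + "/2"] = g.species_id
    roles = {g.species_id: g.role for g in genomes}
    return ReadSet(reads), TruthTable(assignments, roles)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    arr = encode(seq)
    arr[hits] = (arr[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return "".join(_BASES[arr])


# ---------------------------------------------------------------------------
# Study-design preset: one target plus GC-separated contaminants


@dataclass
class Community:
    """A built community: genomes plus the planted ground-truth artifacts."""

    target: GenomeSpec
    contaminants: list[GenomeSpec]
    markers: list[tuple[str, str]]
    marker_sites: GenomeAnnotation
    annotation: GenomeAnnotation
    rrna_reference: list[tuple[str, str]] = field(default_factory=list)

    def genomes(self, target_fraction: float) -> list[GenomeSpec]:
        """All genomes with the target at ``target_fraction`` of the reads and
        contaminants sharing the remainder equally."""
        if not (0.0 < target_fraction < 1.0):
            raise ValueError("target_fraction must be in (0, 1)")
        per = (1.0 - target_fraction) / len(self.contaminants)
        out = [dataclasses.replace(self.target, read_proportion=target_fraction)]
        out += [dataclasses.replace(c, read_proportion=per) for c in self.contaminants]
        return out


def _contaminant_gcs(n: int, center: float = 0.5, gap: float = 0.05) -> list[float]:
    # alternate below/above the target's GC, keeping all pairwise gaps >= gap
    out = []
    for i in range(n):
        step = gap * (i // 2 + 1)
        out.append(center - step if i % 2 == 0 else center + step)
    return out


def build_community(seed: int,
                    n_contaminants: int = 10,
                    target_length: int = 200_000,
                    contaminant_length: int = 100_000,
                    n_markers: int = 5,
                    marker_length: int = 600,
                    n_genes: int = 50,
                    gene_length: int = 900,
                    plant_rrna: bool = False,
                    rrna_length: int = 1_500,
                    gc_gap: float = 0.05,
                    marker_seed_len: int = 15) -> Community:
    """Build the standard study community.

    The target genome (GC 0.5) gets ``n_markers`` random marker genes planted
    verbatim plus ``n_genes`` annotated gene intervals; contaminants are
    GC-separated (pairwise gaps >= ``gc_gap``, alternating around the
    target's GC of 0.5).  Markers are re-drawn until they
    share no ``marker_seed_len``-mer (canonical) with any contaminant genome,
    so marker hits cannot seed on contaminant-derived contigs.
    """
    rng = np.random.default_rng(seed)

    def sub() -> int:
        return int(rng.integers(2**31))

    contaminants = [
        make_random_genome(contaminant_length, gc, sub(),
                           species_id=f"contam{i + 1:02d}", role="contaminant")
        for i, gc in enumerate(_contaminant_gcs(n_contaminants, gap=gc_gap))
    ]
    contam_kmers = _canonical_kmer_union(
        [c.sequence for c in contaminants], marker_seed_len
    )
    markers = []
    for i in range(n_markers):
        for _attempt in range(50):
            seq = random_sequence(marker_length, sub())
            codes, valid = canonical_window_codes(encode(seq), marker_seed_len)
            if not np.isin(codes[valid], contam_kmers).any():
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a contaminant-disjoint marker")
        markers.append((f"marker_{i + 1:02d}", seq))

    target = make_random_genome(target_length, 0.5, sub(),
                                species_id="target", role="target")
    rrna_ref: list[tuple[str, str]] = []
    if plant_rrna:
        planted = []
        for g in [target] + contaminants:
            rseq = random_sequence(rrna_length, sub())
            grown, _ = plant_marker_genes(g, [(f"rrna_{g.species_id}", rseq)], sub())
            planted.append(grown)
            rrna_ref.append((g.species_id, rseq))
        target, contaminants = planted[0], planted[1:]

    target, marker_sites = plant_marker_genes(target, markers, sub())
    annotation = annotate_random_genes(target, n_genes, gene_length, sub())
    return Community(target=target, contaminants=contaminants, markers=markers,
                     marker_sites=marker_sites, annotation=annotation,
                     rrna_reference=rrna_ref)


def _canonical_kmer_union(sequences: list[str], k: int) -> np.ndarray:
    parts = []
    for seq in sequences:
        codes, valid = canonical_window_codes(encode(seq), k)
        parts.append(codes[valid])
    return np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
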