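"""Estimate the number of species-level groups K that fixes the bin count.

The estimator plays the role a small-subunit rRNA survey plays in a full
screening run: reads are similarity-searched against a user-supplied rRNA
reference FASTA, each read is assigned to its best-matching taxon when the
alignment covers at least 90% of the read at the required identity, and K is
the number of taxa collecting at least ``min_hits`` reads.  A manual
override is available for runs where K is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._align import LocalHit, SeedIndex, seed_extend_search
from .io_formats import ReadSet


@dataclass
class RrnaReference:
    """(taxon_id, rRNA sequence) records; taxon ids unique, >= 200 bp each."""

    records: list[tuple[str, str]]

    def __post_init__(self):
        if not self.records:
            raise ValueError("empty rRNA reference")
        ids = [t for t, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids in rRNA reference")
        for t, seq in self.records:
            if len(seq) < 200:
                raise ValueError(f"rRNA sequence for {t} shorter than 200 bp")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SpeciesEstimate:
    K: int
    hit_counts: dict[str, int] = field(default_factory=dict)
    method: str = "reference_hits"  # {reference_hits, manual}

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")


def count_species(reads: ReadSet, ref: RrnaReference,
                  min_identity: float = 0.95, min_hits: int = 5,
                  min_read_fraction: float = 0.9,
                  seed_len: int = 15, seed_step: int = 7) -> SpeciesEstimate:
    """Count taxa with enough rRNA-matching reads.

    A read counts toward a taxon when its best local alignment to that
    taxon's rRNA reaches ``min_identity`` over at least ``min_read_fraction``
    of the read.  Reads matching two taxa equally count for both (K needs
    the taxon set, and double counting cannot shrink it).  If no taxon
    reaches ``min_hits``, K degenerates to 1 with a warning.
    """
    index = SeedIndex(ref.records, seed_len)
    counts = {taxon: 0 for taxon, _ in ref.records}
    for read in reads:
        hits = seed_extend_search([(read.read_id, read.sequence)], index,
                                  step=seed_step)
        best = _qualifying_taxa(hits, len(read), min_identity, min_read_fraction)
        for taxon in best:
            counts[taxon] += 1
    passing = sorted(t for t, c in counts.items() if c >= min_hits)
    if not passing:
        warnings.warn(
            f"no taxon reached min_hits={min_hits}; falling back to K=1"
        )
        return SpeciesEstimate(K=1, hit_counts=counts, method="reference_hits")
    return SpeciesEstimate(K=len(passing), hit_counts=counts,
                           method="reference_hits")


def _qualifying_taxa(hits: list[LocalHit], read_len: int,
                     min_identity: float, min_read_fraction: float) -> list[str]:
    qualifying = [
        h for h in hits
        if h.length >= min_read_fraction * read_len and h.identity >= min_identity
    ]
    if not qualifying:
        return []
    top = max(h.score for h in qualifying)
    return sorted({h.subject_id for h in qualifying if h.score == top})


def override_K(k: int) -> SpeciesEstimate:
    """Manually fix the cluster count."""
    if k < 1:
        raise ValueError("K override must be >= 1")
    return SpeciesEstimate(K=k, hit_counts={}, method="manual")
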