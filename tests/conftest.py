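import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qcblind.io_formats import ReadRecord, ReadSet
from qcblind.pipeline import run_screen
from qcblind.simulate import SimConfig, build_community, simulate_reads
from qcblind.species_count import override_K
from qcblind.target_id import MarkerGene

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_reads(seqs, quality: int = 40) -> ReadSet:
    """Single-end reads with uniform qualities, for unit tests."""
    return ReadSet([
        ReadRecord(f"t{i:04d}", s, np.full(len(s), quality, dtype=np.uint8),
                   "single", f"t{i:04d}")
        for i, s in enumerate(seqs)
    ])


def tile_reads(sequence: str, read_len: int = 100, step: int = 5) -> ReadSet:
    """Error-free reads tiling a sequence densely (every k-mer seen often)."""
    seqs = [sequence[i : i + read_len]
            for i in range(0, len(sequence) - read_len + 1, step)]
    return make_reads(seqs)


@pytest.fixture(scope="session")
def small_community():
    """Three-genome community (1 target + 2 contaminants) with planted
    markers, genes and rRNA, small enough for fast full-pipeline tests."""
    return build_community(seed=7, n_contaminants=2, target_length=40_000,
                           contaminant_length=30_000, n_markers=3,
                           n_genes=10, plant_rrna=True, gc_gap=0.15)


@pytest.fixture(scope="session")
def small_sim(small_community):
    """Reads + truth for the small community at 40% target reads."""
    cfg = SimConfig(coverage=30.0, seed=11)
    reads, truth = simulate_reads(small_community.genomes(0.4), cfg)
    return reads, truth, cfg


@pytest.fixture(scope="session")
def small_run(small_community, small_sim):
    """A fully evaluated pipeline run on the small community."""
    reads, truth, _cfg = small_sim
    markers = [MarkerGene(mid, seq) for mid, seq in small_community.markers]
    return run_screen(
        reads, markers, override_K(3), truth=truth,
        target_genome=(small_community.target.species_id,
                       small_community.target.sequence),
        annotation=small_community.annotation,
    )
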