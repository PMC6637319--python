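"""End-to-end orchestration: trim -> assemble -> prepare -> map/coverage ->
bin -> marker screen -> rescue -> (evaluate), with per-stage accounting.

The in-memory entry point is :func:`run_screen`; :func:`run_pipeline` wraps
it with file I/O for the command line.  :func:`run_gradient_experiment`
reproduces the standard study design — one planted-marker target plus ten
GC-separated contaminants at a gradient of target read proportions — at
desk scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from .assemble import (AssemblyStats, ContigRecord, ContigSet, assembly_stats,
                       build_unitigs, compute_coverage, external_contigs,
                       prepare_contigs, project_alignments)
from .binning import ClusterAssignment, cluster_report, featurize, fit_clusters
from .io_formats import (GenomeAnnotation, ReadSet, TruthTable, read_fasta,
                         read_fastq, read_gff_genes, read_truth, write_fasta,
                         write_fastq, write_tables)
from .preprocess import StageLedger, TrimParams, count_target, trim_set
from .simulate import Community, SimConfig, build_community, simulate_reads
from .species_count import RrnaReference, SpeciesEstimate, count_species, override_K
from .target_id import (MarkerGene, TargetCall, align_markers,
                        call_target_clusters, map_reads, rescue_reads)


@dataclass
class ScreenParams:
    """Every tunable of the screening stages, with the defaults the pipeline
    was designed around."""

    trim: TrimParams = field(default_factory=TrimParams)
    assembler_k: int = 31
    kmer_min_count: int = 2
    min_contig_len: int = 1000
    max_contig_len: int = 10000
    map_min_identity: float = 0.95
    map_seed_len: int = 21
    marker_evalue: float = 1e-20
    min_markers: int = 1
    bin_seed: int = 42
    bin_n_init: int = 10


@dataclass
class ScreenResult:
    """Everything a screening run produces."""

    trimmed: ReadSet
    unitigs: ContigSet
    prepared: ContigSet
    coverage: pd.DataFrame
    assignment: ClusterAssignment | None
    call: TargetCall
    rescued: ReadSet
    alignments: pd.DataFrame  # trimmed reads -> prepared contigs
    ledger: StageLedger
    stats: AssemblyStats | None
    report: ev.EvaluationReport | None = None
    contig_labels: dict[str, str] | None = None


def run_screen(reads: ReadSet,
               markers: list[MarkerGene],
               k_estimate: SpeciesEstimate,
               params: ScreenParams | None = None,
               truth: TruthTable | None = None,
               target_genome: tuple[str, str] | None = None,
               annotation: GenomeAnnotation | None = None,
               contigs: ContigSet | None = None) -> ScreenResult:
    """Run the full screening pipeline on an in-memory read set.

    ``contigs`` supplies externally assembled contigs (they skip the built-in
    assembler but still go through preparation and coverage).  With ``truth``
    the evaluation report is computed; ``target_genome`` and ``annotation``
    additionally enable base and gene coverage.
    """
    if not markers:
        raise ValueError("no marker genes configured")
    params = params or ScreenParams()

    ledger = StageLedger()
    ledger.record("raw", len(reads), count_target(reads, truth))
    trimmed, ledger = trim_set(reads, params.trim, truth=truth, ledger=ledger)

    if contigs is None:
        unitigs = build_unitigs(trimmed, k=params.assembler_k,
                                min_count=params.kmer_min_count)
    else:
        unitigs = contigs
    stats = assembly_stats(unitigs) if len(unitigs) else None

    def _n_target(read_ids) -> int | None:
        if truth is None:
            return None
        return int(pd.Series(read_ids).map(truth.assignments)
                   .isin(set(truth.target_species)).sum())

    unitig_aln = map_reads(trimmed, unitigs,
                           min_identity=params.map_min_identity,
                           seed_len=params.map_seed_len)
    ledger.record("assembly", len(unitig_aln), _n_target(unitig_aln["read_id"]))

    prepared = prepare_contigs(unitigs, params.min_contig_len,
                               params.max_contig_len)
    # alignments onto prepared pieces follow from the unitig alignments and
    # the fragmentation plan (reads straddling a cut are lost)
    alignments = project_alignments(unitig_aln, unitigs,
                                    params.min_contig_len,
                                    params.max_contig_len)
    ledger.record("binning", len(alignments), _n_target(alignments["read_id"]))

    coverage = compute_coverage(prepared, alignments=alignments)

    assignment: ClusterAssignment | None = None
    call = TargetCall(no_target=True)
    rescued = ReadSet([])
    if len(prepared) >= k_estimate.K and len(prepared) > 0:
        feats = featurize(prepared, coverage)
        assignment = fit_clusters(feats, k_estimate.K, seed=params.bin_seed,
                                  n_init=params.bin_n_init)
        hits = align_markers(markers, prepared,
                             evalue_cutoff=params.marker_evalue)
        call = call_target_clusters(hits, assignment,
                                    min_markers=params.min_markers)
        call, rescued = rescue_reads(alignments, call, trimmed)

    # marker-mapping stage: reads whose own best alignment is on a target contig
    on_target = alignments["contig_id"].isin(set(call.target_contigs))
    tgt = (int((on_target & alignments["read_id"].map(truth.assignments)
                .isin(set(truth.target_species))).sum())
           if truth is not None else None)
    ledger.record("marker", int(on_target.sum()), tgt)

    result = ScreenResult(trimmed=trimmed, unitigs=unitigs, prepared=prepared,
                          coverage=coverage, assignment=assignment, call=call,
                          rescued=rescued, alignments=alignments,
                          ledger=ledger, stats=stats)
    if truth is not None and assignment is not None:
        result.contig_labels = ev.label_contigs(prepared, alignments=alignments,
                                                truth=truth)
        result.report = build_report(result, truth, target_genome, annotation,
                                     params)
    return result


def build_report(result: ScreenResult, truth: TruthTable,
                 target_genome: tuple[str, str] | None,
                 annotation: GenomeAnnotation | None,
                 params: ScreenParams) -> ev.EvaluationReport:
    labels = result.contig_labels
    assert labels is not None and result.assignment is not None
    purities = ev.purity(result.assignment, labels, result.alignments)
    conc = ev.concentration(result.assignment, labels, result.alignments, truth)
    dich = ev.dichotomy(result.call, labels, result.alignments, truth)
    cov = None
    if target_genome is not None:
        genome_contig = ContigSet([ContigRecord("__reference__", target_genome[1])])
        read_aln = map_reads(result.rescued, genome_contig,
                             min_identity=params.map_min_identity,
                             seed_len=params.map_seed_len)
        base = ev.base_coverage(read_aln, len(target_genome[1]))
        gene = ev.CoverageScores()
        if annotation is not None and len(annotation):
            target_contigs = ContigSet([
                c for c in result.prepared
                if c.contig_id in set(result.call.target_contigs)
            ])
            intervals = ev.align_contigs_to_reference(target_contigs,
                                                      target_genome)
            gene = ev.gene_coverage(intervals, annotation)
        cov = ev.combine_coverage(base, gene)
    return ev.EvaluationReport(
        purity=ev.purity_frame(purities),
        purity_tiers_contig=ev.purity_tier_counts(purities, "contig"),
        purity_tiers_read=ev.purity_tier_counts(purities, "read"),
        concentration=conc,
        dichotomy=dich,
        coverage=cov,
        data_loss=ev.data_loss(result.ledger),
    )


# ---------------------------------------------------------------------------
# Study-design gradient experiment


@dataclass
class GradientRun:
    target_fraction: float
    sim_seed: int
    result: ScreenResult


def run_gradient_experiment(seed: int,
                            proportions: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95),
                            coverage: float = 50.0,
                            k_clusters: int = 11,
                            params: ScreenParams | None = None,
                            community_kwargs: dict | None = None,
                            read_length: int = 120,
                            fragment_length: int = 200,
                            error_rate: float = 0.0,
                            ) -> tuple[Community, list[GradientRun]]:
    """Simulate and screen the gradient design at each target proportion.

    One community (one planted-marker target plus GC-separated contaminants)
    is built from ``seed``; each proportion is simulated with its own derived
    seed, screened with K fixed at ``k_clusters``, and fully evaluated
    against the simulator's truth.
    """
    rng = np.random.default_rng(seed)
    community = build_community(int(rng.integers(2**31)),
                                **(community_kwargs or {}))
    markers = [MarkerGene(mid, seq) for mid, seq in community.markers]
    runs: list[GradientRun] = []
    for p in proportions:
        sim_seed = int(rng.integers(2**31))
        cfg = SimConfig(read_length=read_length, fragment_length=fragment_length,
                        coverage=coverage, error_rate=error_rate, seed=sim_seed)
        reads, truth = simulate_reads(community.genomes(p), cfg)
        result = run_screen(
            reads, markers, override_K(k_clusters), params=params, truth=truth,
            target_genome=(community.target.species_id, community.target.sequence),
            annotation=community.annotation,
        )
        runs.append(GradientRun(p, sim_seed, result))
    return community, runs


def gradient_metrics(runs: list[GradientRun]) -> pd.DataFrame:
    """Tidy per-proportion summary of the headline metrics."""
    rows = []
    for run in runs:
        rep = run.result.report
        assert rep is not None
        loss = rep.data_loss.set_index("stage")
        rows.append({
            "target_fraction": run.target_fraction,
            "n_reads": len(run.result.trimmed),
            "sensitivity_read_pct": rep.dichotomy.sensitivity_read_pct,
            "specificity_read_pct": rep.dichotomy.specificity_read_pct,
            "sensitivity_contig_pct": rep.dichotomy.sensitivity_contig_pct,
            "specificity_contig_pct": rep.dichotomy.specificity_contig_pct,
            "base_coverage_pct": rep.coverage.base_pct if rep.coverage else np.nan,
            "gene_coverage_pct": rep.coverage.gene_pct if rep.coverage else np.nan,
            "assembly_binning_loss_target_pct":
                float(loss.loc["binning", "cumulative_loss_target_pct"])
                if "binning" in loss.index else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File-based pipeline (CLI backend)


@dataclass
class PipelineConfig:
    """Validated file-level configuration of a full run."""

    reads1: str
    markers_fasta: str
    out_dir: str
    reads2: str | None = None
    contigs_fasta: str | None = None  # external assembly
    rrna_fasta: str | None = None
    set_k: int | None = None
    truth_tsv: str | None = None
    reference_fasta: str | None = None
    genes_path: str | None = None
    seed: int = 42
    params: ScreenParams = field(default_factory=ScreenParams)

    def validate(self) -> None:
        for label, path in (("reads1", self.reads1),
                            ("markers_fasta", self.markers_fasta)):
            if not path or not Path(path).exists():
                raise ValueError(f"{label}: missing required input {path!r}")
        if self.rrna_fasta is None and self.set_k is None:
            raise ValueError("need either an rRNA reference (rrna_fasta) or set_k")
        for path in (self.reads2, self.contigs_fasta, self.rrna_fasta,
                     self.truth_tsv, self.reference_fasta, self.genes_path):
            if path is not None and not Path(path).exists():
                raise ValueError(f"input file not found: {path}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: PipelineConfig) -> ScreenResult:
    """Execute a configured run, writing outputs and a reproducible run log."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reads = read_fastq(config.reads1, config.reads2)
    markers = [MarkerGene(mid, seq) for mid, seq in read_fasta(config.markers_fasta)]
    truth = read_truth(config.truth_tsv) if config.truth_tsv else None
    contigs = None
    if config.contigs_fasta:
        contigs = external_contigs(read_fasta(config.contigs_fasta))
    if config.set_k is not None:
        k_est = override_K(config.set_k)
    else:
        ref = RrnaReference(read_fasta(config.rrna_fasta))
        k_est = count_species(reads, ref)
    target_genome = None
    if config.reference_fasta:
        recs = read_fasta(config.reference_fasta)
        target_genome = recs[0]
    annotation = read_gff_genes(config.genes_path) if config.genes_path else None

    params = dataclasses.replace(config.params, bin_seed=config.seed)
    result = run_screen(reads, markers, k_est, params=params, truth=truth,
                        target_genome=target_genome, annotation=annotation,
                        contigs=contigs)

    # outputs
    if len(result.rescued):
        if any(r.mate != "single" for r in result.rescued):
            write_fastq(result.rescued, out / "target_reads_R1.fastq",
                        out / "target_reads_R2.fastq")
        else:
            write_fastq(result.rescued, out / "target_reads.fastq")
    target_ids = set(result.call.target_contigs)
    write_fasta([(c.contig_id, c.sequence) for c in result.prepared
                 if c.contig_id in target_ids], out / "target_contigs.fasta")
    if result.assignment is not None:
        result.assignment.to_frame().to_csv(out / "clustering.tsv", sep="\t",
                                            index=False)
        cluster_report(result.assignment, result.prepared).to_csv(
            out / "clusters_summary.tsv", sep="\t", index=False)
    with open(out / "target_call.json", "w") as fh:
        json.dump({
            "no_target": result.call.no_target,
            "target_clusters": result.call.target_clusters,
            "n_target_contigs": len(result.call.target_contigs),
            "n_rescued_reads": len(result.call.rescued_read_ids),
            "marker_tally": {str(k): v for k, v in result.call.marker_tally.items()},
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if result.report is not None:
        write_tables(result.report, out / "report")
    with open(out / "run_log.json", "w") as fh:
        json.dump({
            "config": config.to_dict(),
            "K": k_est.K,
            "K_method": k_est.method,
            "ledger": {
                "stages": result.ledger.stages,
                "reads_total": result.ledger.total,
                "reads_target": result.ledger.target,
            },
            "assembly": dataclasses.asdict(result.stats) if result.stats else None,
        }, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return result
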