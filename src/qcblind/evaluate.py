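"""Evaluation of a screening run: purity, target concentration, the
sensitivity/specificity dichotomy, per-stage data loss, and base/gene
coverage of the target genome.

All ratio metrics are ratios of integer counts scaled to percent:

* purity (per cluster): dominant-species contigs (reads) over all contigs
  (reads) in the cluster;
* target concentration (per truth-defined target cluster, TC = a cluster
  holding >= 1 truth-target contig): that TC's target contigs (reads) over
  target contigs (reads) summed over all TCs — the distribution sums to 100;
* sensitivity: truth-target contigs (reads) inside marker-identified
  clusters over all truth-target contigs (reads) present at this stage;
* specificity: truth-target contigs (reads) inside marker-identified
  clusters over everything inside those clusters;
* base coverage: bases of the target genome covered >= 1x by rescued reads
  over genome length;
* gene coverage: annotated genes overlapped >= ``min_overlap_bp`` by a
  target-contig alignment over all annotated genes.

Truth-defined TCs (concentration) and marker-identified target clusters
(dichotomy) are deliberately distinct concepts with distinct names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._align import SeedIndex, best_hit_per_query, seed_extend_search
from .assemble import ContigSet
from .binning import ClusterAssignment
from .io_formats import GenomeAnnotation, TruthTable
from .preprocess import StageLedger
from .target_id import TargetCall

UNKNOWN = "UNKNOWN"


@dataclass
class ClusterPurity:
    cluster_id: int
    dominant_species: str | None
    n_contigs: int
    n_reads: int
    purity_contig_pct: float  # NaN for empty clusters
    purity_read_pct: float


@dataclass
class DichotomyScores:
    sensitivity_contig_pct: float
    sensitivity_read_pct: float
    specificity_contig_pct: float
    specificity_read_pct: float
    no_target: bool = False


@dataclass
class CoverageScores:
    mapped_bases: int = 0
    total_bases: int = 0
    mapped_genes: int = 0
    total_genes: int = 0

    @property
    def base_pct(self) -> float:
        return 100.0 * self.mapped_bases / self.total_bases if self.total_bases else 0.0

    @property
    def gene_pct(self) -> float:
        return 100.0 * self.mapped_genes / self.total_genes if self.total_genes else 0.0


def combine_coverage(base: CoverageScores, gene: CoverageScores) -> CoverageScores:
    return CoverageScores(base.mapped_bases, base.total_bases,
                          gene.mapped_genes, gene.total_genes)


# ---------------------------------------------------------------------------
# Contig labeling


def label_contigs(contigs: ContigSet,
                  alignments: pd.DataFrame | None = None,
                  truth: TruthTable | None = None,
                  references: list[tuple[str, str]] | None = None,
                  min_identity: float = 0.95,
                  min_query_fraction: float = 0.9,
                  seed_len: int = 31) -> dict[str, str]:
    """Assign a source species to every contig.

    Simulated mode (``alignments`` + ``truth``): a contig's species is the
    majority species of its mapped reads, ties to the lexicographically
    smallest species id.  Reference mode (``references`` as (species_id,
    genome) pairs): best whole-contig alignment at >= ``min_identity`` over
    >= ``min_query_fraction`` of the contig.  Unlabeled contigs get
    ``UNKNOWN``.
    """
    if truth is not None and alignments is not None:
        labels = {c.contig_id: UNKNOWN for c in contigs}
        if len(alignments):
            sp = alignments["read_id"].map(truth.assignments)
            tab = (
                pd.DataFrame({"contig_id": alignments["contig_id"], "species": sp})
                .dropna()
                .groupby(["contig_id", "species"])
                .size()
            )
            for cid, grp in tab.groupby(level=0):
                counts = grp.droplevel(0)
                best = counts[counts == counts.max()].index.min()
                if cid in labels:
                    labels[cid] = str(best)
        return labels
    if references is not None:
        index = SeedIndex(references, seed_len)
        step = max(seed_len, 200)
        hits = seed_extend_search(contigs.to_fasta_records(), index, step=step)
        best = best_hit_per_query(hits)
        labels = {}
        for c in contigs:
            h = best.get(c.contig_id)
            ok = (h is not None and h.identity >= min_identity
                  and h.length >= min_query_fraction * len(c))
            labels[c.contig_id] = h.subject_id if ok else UNKNOWN
        return labels
    raise ValueError("need either (alignments, truth) or references to label contigs")


def read_labels(alignments: pd.DataFrame, contig_labels: dict[str, str]) -> pd.Series:
    """Species of each mapped read, inherited from its contig (indexed by read_id)."""
    return pd.Series(
        alignments["contig_id"].map(contig_labels).to_numpy(),
        index=alignments["read_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Purity


def purity(assignment: ClusterAssignment, contig_labels: dict[str, str],
           alignments: pd.DataFrame) -> list[ClusterPurity]:
    """Per-cluster dominant-species purity at contig and read level.

    Reads inherit the species of the contig they map to; reads mapping to
    contigs outside the assignment are ignored.  The dominant species is the
    most frequent contig label (ties to the lexicographically smallest id);
    empty clusters yield NaN purities.
    """
    contig_cluster = assignment.labels
    reads_per_contig = alignments.groupby("contig_id").size()
    out: list[ClusterPurity] = []
    for k in range(assignment.K):
        members = assignment.members(k)
        if not members:
            out.append(ClusterPurity(k, None, 0, 0, float("nan"), float("nan")))
            continue
        clabels = pd.Series({cid: contig_labels.get(cid, UNKNOWN) for cid in members})
        counts = clabels.value_counts()
        top = counts[counts == counts.max()].index.min()
        n_contigs = len(members)
        nreads = {cid: int(reads_per_contig.get(cid, 0)) for cid in members}
        n_reads = sum(nreads.values())
        ds_reads = sum(v for cid, v in nreads.items() if clabels[cid] == top)
        out.append(ClusterPurity(
            cluster_id=k,
            dominant_species=str(top),
            n_contigs=n_contigs,
            n_reads=n_reads,
            purity_contig_pct=100.0 * int(counts.max()) / n_contigs,
            purity_read_pct=(100.0 * ds_reads / n_reads) if n_reads else float("nan"),
        ))
    return out


def purity_tier_counts(purities: list[ClusterPurity],
                       level: str = "contig") -> dict[str, int]:
    """Cumulative counts of clusters at 100 / 90+ / 80+ purity (the 90+ tier
    includes 100%-pure clusters, and 80+ includes both)."""
    attr = f"purity_{level}_pct"
    vals = [getattr(p, attr) for p in purities if not np.isnan(getattr(p, attr))]
    return {
        "100": sum(v >= 100.0 - 1e-9 for v in vals),
        "90+": sum(v >= 90.0 for v in vals),
        "80+": sum(v >= 80.0 for v in vals),
    }


def purity_frame(purities: list[ClusterPurity]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in purities])


# ---------------------------------------------------------------------------
# Target concentration


def concentration(assignment: ClusterAssignment, contig_labels: dict[str, str],
                  alignments: pd.DataFrame, truth: TruthTable) -> pd.DataFrame:
    """Distribution of truth-target contigs and reads over target clusters.

    A target cluster (TC) here is truth-defined: any cluster holding >= 1
    contig labeled with a target species.  Contig and read concentrations
    each sum to 100 over the TCs.
    """
    target_sp = set(truth.target_species)
    tc_contigs: dict[int, int] = {}
    for cid, k in assignment.labels.items():
        if contig_labels.get(cid) in target_sp:
            tc_contigs[k] = tc_contigs.get(k, 0) + 1
    if not tc_contigs:
        raise ValueError("no truth-target contig in any cluster; truth misconfigured")

    is_target_read = alignments["read_id"].map(truth.assignments).isin(target_sp)
    cluster_of_read = alignments["contig_id"].map(assignment.labels)
    read_counts = (
        cluster_of_read[is_target_read].value_counts().to_dict()
    )
    total_contigs = sum(tc_contigs.values())
    total_reads = sum(read_counts.get(k, 0) for k in tc_contigs)
    rows = []
    for k in sorted(tc_contigs):
        nc = tc_contigs[k]
        nr = int(read_counts.get(k, 0))
        rows.append({
            "cluster_id": k,
            "n_target_contigs": nc,
            "n_target_reads": nr,
            "concentration_contig_pct": 100.0 * nc / total_contigs,
            "concentration_read_pct": (100.0 * nr / total_reads) if total_reads else 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity / specificity


def dichotomy(call: TargetCall, contig_labels: dict[str, str],
              alignments: pd.DataFrame, truth: TruthTable) -> DichotomyScores:
    """Sensitivity and specificity of the marker-identified target clusters.

    Contig level counts prepared contigs; read level counts reads by their
    own (truth) species, with membership given by the contig their best
    alignment lands on.  Denominators are the truth-target items present at
    this stage: all labeled contigs, and all mapped reads.
    """
    if call.no_target:
        return DichotomyScores(0.0, 0.0, 0.0, 0.0, no_target=True)
    target_sp = set(truth.target_species)
    marker_contigs = set(call.target_contigs)

    all_target_contigs = sum(1 for sp in contig_labels.values() if sp in target_sp)
    tp_contigs = sum(
        1 for cid in marker_contigs if contig_labels.get(cid) in target_sp
    )
    in_marker = alignments["contig_id"].isin(marker_contigs)
    is_target = alignments["read_id"].map(truth.assignments).isin(target_sp)
    tp_reads = int((in_marker & is_target).sum())
    all_marker_reads = int(in_marker.sum())
    all_target_reads = int(is_target.sum())

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return DichotomyScores(
        sensitivity_contig_pct=pct(tp_contigs, all_target_contigs),
        sensitivity_read_pct=pct(tp_reads, all_target_reads),
        specificity_contig_pct=pct(tp_contigs, len(marker_contigs)),
        specificity_read_pct=pct(tp_reads, all_marker_reads),
    )


# ---------------------------------------------------------------------------
# Coverage


def interval_union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    if not intervals:
        return 0
    arr = sorted(intervals)
    total = 0
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def base_coverage(read_alignments: pd.DataFrame, genome_length: int) -> CoverageScores:
    """Fraction of target-genome bases covered >= 1x by rescued reads.

    ``read_alignments`` are alignments of the rescued reads onto the target
    reference genome (columns start/end, 0-based half-open).
    """
    intervals = list(zip(read_alignments["start"].astype(int),
                         read_alignments["end"].astype(int)))
    mb = interval_union_length(intervals)
    return CoverageScores(mapped_bases=mb, total_bases=int(genome_length))


def gene_coverage(contig_intervals: list[tuple[int, int]],
                  annotation: GenomeAnnotation,
                  min_overlap_bp: int = 1) -> CoverageScores:
    """Fraction of annotated genes overlapped by target-contig alignments.

    A gene counts as mapped when a single aligned interval overlaps it by at
    least ``min_overlap_bp``.
    """
    if len(annotation) == 0:
        raise ValueError("empty gene annotation")
    tree = IntervalTree()
    for s, e in contig_intervals:
        if e > s:
            tree.addi(int(s), int(e))
    mapped = 0
    for _gid, gs, ge, _strand in annotation.genes:
        for iv in tree.overlap(gs, ge):
            if min(iv.end, ge) - max(iv.begin, gs) >= min_overlap_bp:
                mapped += 1
                break
    return CoverageScores(mapped_genes=mapped, total_genes=len(annotation))


def align_contigs_to_reference(contigs: ContigSet, genome: tuple[str, str],
                               seed_len: int = 31,
                               step: int = 200) -> list[tuple[int, int]]:
    """Best-placement intervals of contigs on a reference genome (for gene
    coverage); contigs with no seeded placement are skipped."""
    index = SeedIndex([genome], seed_len)
    hits = seed_extend_search(contigs.to_fasta_records(), index, step=step)
    best = best_hit_per_query(hits)
    return [(h.s_start, h.s_end) for h in best.values()]


# ---------------------------------------------------------------------------
# Data loss


def data_loss(ledger: StageLedger) -> pd.DataFrame:
    """Marginal and cumulative loss per pipeline stage, total and (when the
    ledger carries truth counts) target-only."""
    df = ledger.to_frame()
    out = df.copy()
    for col, name in (("reads_total", "total"), ("reads_target", "target")):
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            out[f"marginal_loss_{name}_pct"] = np.nan
            out[f"cumulative_loss_{name}_pct"] = np.nan
            continue
        prev = np.concatenate(([vals[0]], vals[:-1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            marg = 100.0 * (1.0 - np.divide(vals, prev, out=np.ones_like(vals),
                                            where=prev > 0))
            cum = 100.0 * (1.0 - np.divide(vals, vals[0],
                                           out=np.ones_like(vals),
                                           where=vals[0] > 0))
        out[f"marginal_loss_{name}_pct"] = marg
        out[f"cumulative_loss_{name}_pct"] = cum
    return out


# ---------------------------------------------------------------------------
# Report


@dataclass
class EvaluationReport:
    """Bundle of every evaluation output for one run."""

    purity: pd.DataFrame
    purity_tiers_contig: dict[str, int]
    purity_tiers_read: dict[str, int]
    concentration: pd.DataFrame
    dichotomy: DichotomyScores
    coverage: CoverageScores | None
    data_loss: pd.DataFrame

    def to_frames(self) -> dict[str, pd.DataFrame]:
        frames = {
            "purity": self.purity,
            "concentration": self.concentration,
            "dichotomy": pd.DataFrame([{
                "level": lvl,
                "sensitivity_pct": getattr(self.dichotomy, f"sensitivity_{lvl}_pct"),
                "specificity_pct": getattr(self.dichotomy, f"specificity_{lvl}_pct"),
            } for lvl in ("contig", "read")]),
            "data_loss": self.data_loss,
        }
        if self.coverage is not None:
            frames["coverage"] = pd.DataFrame([
                {"metric": "base", "mapped": self.coverage.mapped_bases,
                 "total": self.coverage.total_bases,
                 "coverage_pct": self.coverage.base_pct},
                {"metric": "gene", "mapped": self.coverage.mapped_genes,
                 "total": self.coverage.total_genes,
                 "coverage_pct": self.coverage.gene_pct},
            ])
        return frames

    def summary(self) -> dict:
        s = {
            "purity_tiers_contig": self.purity_tiers_contig,
            "purity_tiers_read": self.purity_tiers_read,
            "sensitivity_contig_pct": self.dichotomy.sensitivity_contig_pct,
            "sensitivity_read_pct": self.dichotomy.sensitivity_read_pct,
            "specificity_contig_pct": self.dichotomy.specificity_contig_pct,
            "specificity_read_pct": self.dichotomy.specificity_read_pct,
            "no_target": self.dichotomy.no_target,
        }
        if self.coverage is not None:
            s["base_coverage_pct"] = self.coverage.base_pct
            s["gene_coverage_pct"] = self.coverage.gene_pct
        if len(self.data_loss):
            s["data_loss"] = {
                row["stage"]: {
                    "cumulative_loss_target_pct": row.get("cumulative_loss_target_pct"),
                    "cumulative_loss_total_pct": row.get("cumulative_loss_total_pct"),
                }
                for _, row in self.data_loss.iterrows()
            }
        return s
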