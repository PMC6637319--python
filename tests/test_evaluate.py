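import numpy as np
import pandas as pd
import pytest

from qcblind.assemble import ContigRecord, ContigSet
from qcblind.binning import ClusterAssignment
from qcblind.evaluate import (ClusterPurity, CoverageScores, base_coverage,
                              concentration, data_loss, dichotomy,
                              gene_coverage, interval_union_length,
                              label_contigs, purity, purity_tier_counts)
from qcblind.io_formats import GenomeAnnotation, TruthTable
from qcblind.preprocess import StageLedger
from qcblind.simulate import random_sequence
from qcblind.target_id import TargetCall


def assignment_for(labels: dict[str, int], K: int) -> ClusterAssignment:
    resp = pd.DataFrame(np.eye(K)[list(labels.values())],
                        index=list(labels), columns=range(K))
    return ClusterAssignment(K=K, labels=labels, responsibilities=resp, seed=0)


def aln(rows):
    return pd.DataFrame(rows, columns=["read_id", "contig_id", "start", "end"])


# ---------------------------------------------------------------------------
# Contig labeling


def test_contig_label_is_majority_species():
    truth = TruthTable({"r1": "X", "r2": "X", "r3": "Y"},
                       {"X": "target", "Y": "contaminant"})
    a = aln([("r1", "c1", 0, 100), ("r2", "c1", 10, 110), ("r3", "c1", 20, 120)])
    contigs = ContigSet([ContigRecord("c1", "ACGT" * 100)])
    assert label_contigs(contigs, alignments=a, truth=truth) == {"c1": "X"}


def test_chimeric_contig_takes_majority_and_tie_breaks_lexicographically():
    truth = TruthTable({f"r{i}": ("X" if i < 6 else "Y") for i in range(10)},
                       {"X": "target", "Y": "contaminant"})
    rows = [(f"r{i}", "c1", 0, 100) for i in range(10)]
    contigs = ContigSet([ContigRecord("c1", "ACGT" * 100)])
    assert label_contigs(contigs, alignments=aln(rows), truth=truth) == {"c1": "X"}
    # exact tie: 5 vs 5 -> lexicographically smaller species id
    truth2 = TruthTable({f"r{i}": ("X" if i < 5 else "Y") for i in range(10)},
                        {"X": "target", "Y": "contaminant"})
    assert label_contigs(contigs, alignments=aln(rows), truth=truth2) == {"c1": "X"}


def test_unmapped_contig_is_unknown():
    truth = TruthTable({"r1": "X"}, {"X": "target"})
    contigs = ContigSet([ContigRecord("c1", "ACGT" * 100),
                         ContigRecord("c2", "TTAA" * 100)])
    labels = label_contigs(contigs, alignments=aln([("r1", "c1", 0, 100)]),
                           truth=truth)
    assert labels == {"c1": "X", "c2": "UNKNOWN"}


def test_reference_mode_labels_by_best_alignment():
    ga = random_sequence(5_000, seed=41)
    gb = random_sequence(5_000, seed=42)
    contigs = ContigSet([ContigRecord("c1", ga[1000:3000]),
                         ContigRecord("c2", gb[500:2500]),
                         ContigRecord("c3", random_sequence(2_000, seed=43))])
    labels = label_contigs(contigs, references=[("A", ga), ("B", gb)])
    assert labels == {"c1": "A", "c2": "B", "c3": "UNKNOWN"}


def test_no_truth_source_is_an_error():
    with pytest.raises(ValueError):
        label_contigs(ContigSet([ContigRecord("c1", "ACGT")]))


# ---------------------------------------------------------------------------
# Purity


def test_purity_arithmetic():
    labels = {f"c{i}": 0 for i in range(10)}
    contig_species = {f"c{i}": ("X" if i < 8 else "Y") for i in range(10)}
    rows = [(f"r{i}", f"c{i % 10}", 0, 100) for i in range(20)]
    out = purity(assignment_for(labels, 1), contig_species, aln(rows))
    assert out[0].dominant_species == "X"
    assert out[0].purity_contig_pct == pytest.approx(80.0)
    # reads inherit contig labels: 16 of 20 reads sit on X contigs
    assert out[0].purity_read_pct == pytest.approx(80.0)


def test_pure_cluster_is_100():
    labels = {f"c{i}": 0 for i in range(10)}
    species = {f"c{i}": "X" for i in range(10)}
    out = purity(assignment_for(labels, 1), species, aln([]))
    assert out[0].purity_contig_pct == 100.0
    assert np.isnan(out[0].purity_read_pct)  # no mapped reads


def test_empty_cluster_row_is_nan():
    out = purity(assignment_for({"c0": 0}, 2), {"c0": "X"}, aln([]))
    assert out[1].dominant_species is None
    assert np.isnan(out[1].purity_contig_pct)


def test_purity_tiers_are_cumulative():
    rows = [ClusterPurity(i, "X", 1, 1, p, p)
            for i, p in enumerate([100.0, 95.0, 85.0, 70.0])]
    tiers = purity_tier_counts(rows, "contig")
    assert tiers == {"100": 1, "90+": 2, "80+": 3}


# ---------------------------------------------------------------------------
# Concentration


def test_concentration_distribution_sums_to_100():
    labels = {f"c{i}": (0 if i < 94 else 1) for i in range(100)}
    species = {cid: "T" for cid in labels}
    truth = TruthTable({}, {"T": "target"})
    out = concentration(assignment_for(labels, 2), species, aln([]), truth)
    assert out["concentration_contig_pct"].tolist() == [94.0, 6.0]
    assert out["concentration_contig_pct"].sum() == pytest.approx(100.0)


def test_concentration_single_cluster_gets_everything():
    labels = {"c1": 0, "c2": 0, "c3": 1}
    species = {"c1": "T", "c2": "T", "c3": "C"}
    truth = TruthTable({"r1": "T"}, {"T": "target", "C": "contaminant"})
    out = concentration(assignment_for(labels, 2), species,
                        aln([("r1", "c1", 0, 100)]), truth)
    assert out["cluster_id"].tolist() == [0]
    assert out["concentration_contig_pct"].tolist() == [100.0]
    assert out["concentration_read_pct"].tolist() == [100.0]


def test_concentration_without_target_contigs_is_error():
    truth = TruthTable({}, {"T": "target"})
    with pytest.raises(ValueError, match="truth"):
        concentration(assignment_for({"c1": 0}, 1), {"c1": "C"}, aln([]), truth)


# ---------------------------------------------------------------------------
# Dichotomy


def test_dichotomy_textbook_case():
    # marker clusters contain 90 target + 5 contaminant contigs; 100 target
    # contigs exist in total -> sensitivity 90.0, specificity 94.7
    labels = {}
    species = {}
    for i in range(90):
        labels[f"t{i}"], species[f"t{i}"] = 0, "T"
    for i in range(90, 100):
        labels[f"t{i}"], species[f"t{i}"] = 1, "T"
    for i in range(5):
        labels[f"f{i}"], species[f"f{i}"] = 0, "C"
    call = TargetCall(target_clusters=[0],
                      target_contigs=[c for c, k in labels.items() if k == 0])
    truth = TruthTable({}, {"T": "target", "C": "contaminant"})
    d = dichotomy(call, species, aln([]), truth)
    assert d.sensitivity_contig_pct == pytest.approx(90.0)
    assert round(d.specificity_contig_pct, 1) == 94.7


def test_dichotomy_perfect_case_reads():
    labels = {"c1": 0, "c2": 1}
    species = {"c1": "T", "c2": "C"}
    truth = TruthTable({"r1": "T", "r2": "T", "r3": "C"},
                       {"T": "target", "C": "contaminant"})
    rows = aln([("r1", "c1", 0, 100), ("r2", "c1", 0, 100), ("r3", "c2", 0, 100)])
    call = TargetCall(target_clusters=[0], target_contigs=["c1"])
    d = dichotomy(call, species, rows, truth)
    assert d.sensitivity_read_pct == 100.0
    assert d.specificity_read_pct == 100.0


def test_dichotomy_no_target_flag():
    truth = TruthTable({}, {"T": "target"})
    d = dichotomy(TargetCall(no_target=True), {}, aln([]), truth)
    assert d.no_target and d.sensitivity_read_pct == 0.0


def test_dichotomy_matches_bruteforce_confusion_matrix(small_run, small_sim):
    _reads, truth, _ = small_sim
    d = small_run.report.dichotomy
    labels = small_run.contig_labels
    target_contigs = set(small_run.call.target_contigs)
    target_sp = set(truth.target_species)
    # naive recount from raw tables
    tp = fp = 0
    for _, row in small_run.alignments.iterrows():
        if row["contig_id"] in target_contigs:
            if truth.assignments[row["read_id"]] in target_sp:
                tp += 1
            else:
                fp += 1
    all_t = sum(truth.assignments[r] in target_sp
                for r in small_run.alignments["read_id"])
    assert d.sensitivity_read_pct == pytest.approx(100.0 * tp / all_t)
    assert d.specificity_read_pct == pytest.approx(100.0 * tp / (tp + fp))
    tp_c = sum(labels[c] in target_sp for c in target_contigs)
    all_c = sum(sp in target_sp for sp in labels.values())
    assert d.sensitivity_contig_pct == pytest.approx(100.0 * tp_c / all_c)
    assert d.specificity_contig_pct == pytest.approx(
        100.0 * tp_c / len(target_contigs))


# ---------------------------------------------------------------------------
# Coverage


def test_base_coverage_examples():
    tiling = aln([(f"r{i}", "g", s, s + 100) for i, s in
                  enumerate(range(0, 1000, 100))])
    assert base_coverage(tiling, 1_000).base_pct == 100.0
    single = aln([("r0", "g", 100, 220)])
    assert base_coverage(single, 1_000).base_pct == pytest.approx(12.0)
    assert base_coverage(aln([]), 1_000).base_pct == 0.0


def test_interval_union_matches_bitmap_oracle():
    rng = np.random.default_rng(5)
    n = 50_000
    starts = rng.integers(0, n - 200, size=300)
    intervals = [(int(s), int(s + rng.integers(50, 200))) for s in starts]
    bitmap = np.zeros(n, dtype=bool)
    for s, e in intervals:
        bitmap[s:e] = True
    assert interval_union_length(intervals) == int(bitmap.sum())


def test_base_coverage_monotone_in_read_set():
    rows = [(f"r{i}", "g", i * 37 % 900, i * 37 % 900 + 100) for i in range(50)]
    prev = 0
    for upto in (10, 25, 50):
        mb = base_coverage(aln(rows[:upto]), 1_000).mapped_bases
        assert mb >= prev
        prev = mb


def test_gene_coverage_overlap_rules():
    ann = GenomeAnnotation("g", [("g1", 100, 200, "+"), ("g2", 500, 600, "+"),
                                 ("g3", 900, 1000, "+")])
    cov = gene_coverage([(0, 250), (580, 620)], ann)
    # g1 inside an interval, g2 overlapped by 20 bp, g3 disjoint
    assert cov.mapped_genes == 2 and cov.total_genes == 3
    assert cov.gene_pct == pytest.approx(100.0 * 2 / 3)
    strict = gene_coverage([(0, 250), (580, 620)], ann, min_overlap_bp=50)
    assert strict.mapped_genes == 1


def test_gene_coverage_empty_annotation_is_error():
    with pytest.raises(ValueError):
        gene_coverage([(0, 10)], GenomeAnnotation("g", []))


def test_all_planted_genes_recovered_on_clean_run(small_run):
    cov = small_run.report.coverage
    assert cov.gene_pct == 100.0
    assert cov.mapped_genes == cov.total_genes == 10


# ---------------------------------------------------------------------------
# Data loss


def test_data_loss_zero_when_nothing_lost():
    led = StageLedger()
    led.record("raw", 100, 40)
    led.record("trim", 100, 40)
    out = data_loss(led)
    assert out["cumulative_loss_total_pct"].tolist() == [0.0, 0.0]
    assert out["cumulative_loss_target_pct"].tolist() == [0.0, 0.0]


def test_data_loss_arithmetic():
    led = StageLedger()
    led.record("raw", 200, 100)
    led.record("marker", 180, 95)
    out = data_loss(led).set_index("stage")
    assert out.loc["marker", "cumulative_loss_target_pct"] == pytest.approx(5.0)
    assert out.loc["marker", "cumulative_loss_total_pct"] == pytest.approx(10.0)


def test_marginal_losses_compose_to_cumulative():
    led = StageLedger()
    for stage, n in [("raw", 1000), ("trim", 930), ("assembly", 870),
                     ("binning", 860), ("marker", 700)]:
        led.record(stage, n)
    out = data_loss(led)
    surv = np.prod(1 - out["marginal_loss_total_pct"].to_numpy() / 100.0)
    cum = 1 - out["cumulative_loss_total_pct"].iloc[-1] / 100.0
    assert surv == pytest.approx(cum)
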