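import math

import numpy as np
import pandas as pd
import pytest

from qcblind._align import K_PARAM, karlin_altschul_lambda
from qcblind.assemble import ContigRecord, ContigSet
from qcblind.binning import ClusterAssignment
from qcblind.io_formats import ReadRecord, ReadSet
from qcblind.simulate import random_sequence
from qcblind.target_id import (MarkerGene, MarkerHit, TargetCall,
                               align_markers, call_target_clusters, map_reads,
                               read_tabular_hits, rescue_reads)

from conftest import make_reads

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(_COMP)[::-1]


def kmers(s, k=15):
    return {s[i : i + k] for i in range(len(s) - k + 1)} | \
           {rc(s)[i : i + k] for i in range(len(s) - k + 1)}


def assignment_for(labels: dict[str, int], K: int) -> ClusterAssignment:
    resp = pd.DataFrame(np.eye(K)[list(labels.values())],
                        index=list(labels), columns=range(K))
    return ClusterAssignment(K=K, labels=labels, responsibilities=resp, seed=0)


# ---------------------------------------------------------------------------
# Marker alignment


def test_planted_marker_found_at_full_identity():
    marker = random_sequence(600, seed=1)
    contig = random_sequence(2_000, seed=2) + marker + random_sequence(2_000, seed=3)
    hits = align_markers([MarkerGene("m1", marker)],
                         ContigSet([ContigRecord("c1", contig)]))
    assert len(hits) == 1
    h = hits[0]
    assert h.identity == 1.0 and h.length == 600
    assert h.evalue <= 1e-20


def test_marker_on_reverse_strand_found():
    marker = random_sequence(600, seed=4)
    contig = random_sequence(1_000, seed=5) + rc(marker) + random_sequence(1_000, seed=6)
    hits = align_markers([MarkerGene("m1", marker)],
                         ContigSet([ContigRecord("c1", contig)]))
    assert len(hits) == 1 and hits[0].identity == 1.0


def test_no_shared_seed_means_no_hit():
    marker = random_sequence(600, seed=7)
    contig = random_sequence(5_000, seed=8)
    # exhaustive 15-mer intersection oracle
    assert not (kmers(marker) & kmers(contig))
    hits = align_markers([MarkerGene("m1", marker)],
                         ContigSet([ContigRecord("c1", contig)]))
    assert hits == []


def test_short_exact_match_fails_significance():
    marker = random_sequence(600, seed=9)
    snippet = marker[100:120]  # 20 bp exact
    contig = random_sequence(2_500, seed=10) + snippet + random_sequence(2_500, seed=11)
    assert not (kmers(marker) & kmers(contig.replace(snippet, "")))
    contigs = ContigSet([ContigRecord("c1", contig)])
    assert align_markers([MarkerGene("m1", marker)], contigs) == []
    # independent check with the documented significance formula:
    # even a perfect 20-base score cannot reach 1e-20 against these sizes
    lam = karlin_altschul_lambda(1, -2)
    e20 = K_PARAM * 600 * len(contig) * math.exp(-lam * 20)
    assert e20 > 1e-20


def test_evalue_threshold_scales_with_match_length():
    # independent bisection of (1/4)e^l - 1 + (3/4)e^(-2l) = 0
    lo, hi = 1e-6, 10.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if 0.25 * math.exp(mid) + 0.75 * math.exp(-2 * mid) < 1.0:
            lo = mid
        else:
            hi = mid
    lam = karlin_altschul_lambda(1, -2)
    assert lam == pytest.approx((lo + hi) / 2, abs=1e-6)
    # a few hundred exact bases is astronomically significant
    assert K_PARAM * 600 * 1e7 * math.exp(-lam * 300) < 1e-100


def test_empty_contig_set_warns():
    with pytest.warns(UserWarning):
        assert align_markers([MarkerGene("m", "A" * 200)], ContigSet([])) == []


def test_marker_validation():
    with pytest.raises(ValueError, match="100"):
        MarkerGene("m", "ACGT")
    with pytest.raises(ValueError, match="duplicate"):
        align_markers([MarkerGene("m", "A" * 200), MarkerGene("m", "C" * 200)],
                      ContigSet([ContigRecord("c", "ACGT" * 100)]))
    with pytest.raises(ValueError, match="marker"):
        align_markers([], ContigSet([ContigRecord("c", "ACGT" * 100)]))


def test_external_tabular_hits_filtered_at_cutoff(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text(
        "m1\tc1\t100.0\t600\t0\t0\t1\t600\t10\t609\t1e-300\t1100\n"
        "m2\tc2\t95.0\t200\t10\t0\t1\t200\t1\t200\t1e-5\t180\n"
    )
    hits = read_tabular_hits(p)
    assert [h.marker_id for h in hits] == ["m1"]
    assert hits[0].identity == 1.0


def test_external_sam_alignments_drop_in(tmp_path):
    from qcblind.target_id import read_sam_alignments

    p = tmp_path / "aln.sam"
    p.write_text(
        "@HD\tVN:1.6\n"
        "@SQ\tSN:c1\tLN:1000\n"
        "r1\t0\tc1\t101\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:2\n"
        "r2\t16\tc1\t201\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:0\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 100 + "\t*\n"          # unmapped
        "r4\t0\tc1\t301\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:20\n"
    )
    aln = read_sam_alignments(p)
    assert aln["read_id"].tolist() == ["r1", "r2"]  # r4 below identity floor
    assert aln["start"].tolist() == [100, 200]  # SAM 1-based -> half-open
    assert aln["strand"].tolist() == ["+", "-"]
    assert aln["identity"].tolist() == [0.98, 1.0]


# ---------------------------------------------------------------------------
# Target-cluster calling


def test_all_markers_in_one_cluster():
    labels = {f"c{i}": i % 3 for i in range(9)}
    hits = [MarkerHit(f"m{j}", "c0", 600, 1.0, 600, 1e-300) for j in range(7)]
    call = call_target_clusters(hits, assignment_for(labels, 3))
    assert call.target_clusters == [0]
    assert call.target_contigs == sorted(c for c, k in labels.items() if k == 0)


def test_hits_spread_over_three_clusters_all_called():
    labels = {"a": 0, "b": 1, "c": 2, "d": 3}
    hits = [MarkerHit("m1", "a", 600, 1.0, 600, 1e-300),
            MarkerHit("m2", "b", 600, 1.0, 600, 1e-300),
            MarkerHit("m3", "c", 600, 1.0, 600, 1e-300)]
    call = call_target_clusters(hits, assignment_for(labels, 4))
    assert call.target_clusters == [0, 1, 2]


def test_no_hits_is_explicit_no_target():
    call = call_target_clusters([], assignment_for({"a": 0}, 1))
    assert call.no_target and call.target_clusters == []


def test_min_markers_monotone():
    labels = {"a": 0, "b": 1}
    hits = [MarkerHit("m1", "a", 600, 1.0, 600, 1e-300),
            MarkerHit("m2", "a", 600, 1.0, 600, 1e-300),
            MarkerHit("m1", "b", 600, 1.0, 600, 1e-300)]
    sizes = []
    for mm in (1, 2, 3):
        call = call_target_clusters(hits, assignment_for(labels, 2),
                                    min_markers=mm)
        sizes.append(len(call.target_clusters))
    assert sizes == sorted(sizes, reverse=True)
    assert sizes[0] == 2 and sizes[1] == 1 and sizes[2] == 0


# ---------------------------------------------------------------------------
# Read mapping


def test_exact_read_maps_with_coordinates():
    contig = random_sequence(3_000, seed=20)
    reads = make_reads([contig[500:620]])
    aln = map_reads(reads, ContigSet([ContigRecord("c1", contig)]))
    row = aln.iloc[0]
    assert (row.contig_id, row.start, row.end, row.identity, row.strand) == \
           ("c1", 500, 620, 1.0, "+")


def test_reverse_strand_read_maps():
    contig = random_sequence(3_000, seed=21)
    reads = make_reads([rc(contig[500:620])])
    aln = map_reads(reads, ContigSet([ContigRecord("c1", contig)]))
    assert aln.iloc[0].strand == "-"
    assert (aln.iloc[0].start, aln.iloc[0].end) == (500, 620)


def test_foreign_read_unmapped():
    contig = random_sequence(3_000, seed=22)
    foreign = random_sequence(120, seed=23)
    assert not (kmers(foreign, 21) & kmers(contig, 21))  # seed oracle
    aln = map_reads(make_reads([foreign]), ContigSet([ContigRecord("c1", contig)]))
    assert len(aln) == 0


def test_tie_broken_by_lowest_contig_id():
    contig = random_sequence(2_000, seed=24)
    reads = make_reads([contig[100:220]])
    cs = ContigSet([ContigRecord("c2", contig), ContigRecord("c1", contig)])
    aln = map_reads(reads, cs)
    assert aln.iloc[0].contig_id == "c1"


def test_mismatched_read_respects_identity_floor():
    contig = random_sequence(3_000, seed=25)
    read = list(contig[500:620])
    for pos in (60, 70, 80, 90, 100, 110, 111, 112):  # 8 mismatches: 93.3%
        read[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[pos]]
    aln = map_reads(make_reads(["".join(read)]),
                    ContigSet([ContigRecord("c1", contig)]), min_identity=0.95)
    assert len(aln) == 0
    aln = map_reads(make_reads(["".join(read)]),
                    ContigSet([ContigRecord("c1", contig)]), min_identity=0.90)
    assert len(aln) == 1 and aln.iloc[0].identity == pytest.approx(112 / 120)


# ---------------------------------------------------------------------------
# Rescue


def paired_reads(specs):
    """specs: list of (pair_id, seq1, seq2)."""
    out = []
    for pid, s1, s2 in specs:
        q1 = np.full(len(s1), 40, dtype=np.uint8)
        q2 = np.full(len(s2), 40, dtype=np.uint8)
        out.append(ReadRecord(pid + "/1", s1, q1, "mate1", pid))
        out.append(ReadRecord(pid + "/2", s2, q2, "mate2", pid))
    return ReadSet(out)


def test_rescue_pair_rules():
    target = random_sequence(3_000, seed=30)
    other = random_sequence(3_000, seed=31)
    foreign = random_sequence(120, seed=32)
    reads = paired_reads([
        ("p1", target[0:120], rc(target[200:320])),   # both on target
        ("p2", target[400:520], foreign),             # mate2 unmapped
        ("p3", other[0:120], rc(other[200:320])),     # both on non-target
    ])
    contigs = ContigSet([ContigRecord("t1", target), ContigRecord("x1", other)])
    aln = map_reads(reads, contigs)
    call = TargetCall(target_clusters=[0], target_contigs=["t1"])
    call, rescued = rescue_reads(aln, call, reads)
    assert sorted(call.rescued_read_ids) == ["p1/1", "p1/2", "p2/1", "p2/2"]
    # rescued reads are a subset of pairs with a target-mapped mate
    mapped = set(aln["read_id"])
    for r1, r2 in rescued.pairs():
        assert r1.read_id in mapped or r2.read_id in mapped


def test_rescue_no_target_is_empty():
    reads = paired_reads([("p1", "A" * 120, "C" * 120)])
    call, rescued = rescue_reads(pd.DataFrame(columns=["read_id", "contig_id"]),
                                 TargetCall(no_target=True), reads)
    assert len(rescued) == 0 and call.no_target
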