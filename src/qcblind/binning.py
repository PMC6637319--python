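"""Composition + coverage contig binning into K species-level clusters.

Each prepared contig is featurized as its canonical tetranucleotide
frequency profile (136 dimensions after reverse-complement collapsing,
pseudocount-smoothed and log-transformed) concatenated with log(depth + 1)
per sample, on their natural log scales.  Features are
PCA-reduced to 90% retained variance and clustered with a diagonal-covariance
Gaussian mixture at a fixed K (K comes from the species-count stage), taking
the best of ``n_init`` seeded restarts by log-likelihood.  Every contig is
hard-assigned to its maximum-responsibility component; ties break to the
lowest cluster id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from ._kmers import canonical_window_codes, encode, window_codes
from .assemble import ContigSet

_K4 = 4


def _canonical_4mer_classes() -> tuple[np.ndarray, int]:
    """Lookup from 4-mer code (0..255) to canonical class index (0..135)."""
    codes = np.arange(256, dtype=np.uint64)
    # reverse complement of a 4-mer code
    rc = np.zeros(256, dtype=np.uint64)
    for p in range(4):
        base = (codes >> np.uint64(2 * (3 - p))) & np.uint64(3)
        rc |= (np.uint64(3) - base) << np.uint64(2 * p)
    canon = np.minimum(codes, rc)
    classes = np.unique(canon)
    lookup = np.searchsorted(classes, canon).astype(np.int64)
    return lookup, len(classes)


_CLASS_LOOKUP, N_COMPOSITION = _canonical_4mer_classes()  # N_COMPOSITION == 136


@dataclass
class ContigFeatures:
    contig_id: str
    composition: np.ndarray  # log canonical 4-mer frequencies (136,)
    coverage: np.ndarray  # log(depth + 1), one entry per sample


@dataclass
class ClusterAssignment:
    """A hard contig -> cluster partition plus posterior responsibilities."""

    K: int
    labels: dict[str, int]
    responsibilities: pd.DataFrame  # index contig_id, columns 0..K-1
    seed: int

    def members(self, cluster_id: int) -> list[str]:
        return [cid for cid, c in self.labels.items() if c == cluster_id]

    def cluster_of(self, contig_id: str) -> int:
        return self.labels[contig_id]

    def to_frame(self) -> pd.DataFrame:
        resp_max = self.responsibilities.max(axis=1)
        return pd.DataFrame({
            "contig_id": list(self.labels.keys()),
            "cluster_id": list(self.labels.values()),
            "max_responsibility": [float(resp_max[c]) for c in self.labels],
        })


def featurize(contigs: ContigSet, coverage: pd.DataFrame,
              pseudocount: float = 1.0) -> list[ContigFeatures]:
    """Build per-contig composition + coverage features.

    ``coverage`` is the tidy frame from :func:`qcblind.assemble.compute_coverage`
    (contig_id, sample, mean_depth); one coverage dimension per sample.
    """
    depth = coverage.pivot(index="contig_id", columns="sample", values="mean_depth")
    feats = []
    for c in contigs:
        if len(c) < 4:
            raise ValueError(f"contig {c.contig_id} shorter than 4 bp")
        codes, valid = window_codes(encode(c.sequence), _K4)
        counts = np.bincount(_CLASS_LOOKUP[codes[valid].astype(np.int64)],
                             minlength=N_COMPOSITION).astype(float)
        counts += pseudocount
        freqs = counts / counts.sum()
        if c.contig_id not in depth.index:
            raise ValueError(f"no coverage for contig {c.contig_id}")
        d = depth.loc[c.contig_id].to_numpy(dtype=float)
        feats.append(ContigFeatures(c.contig_id, np.log(freqs), np.log1p(d)))
    return feats


def _feature_matrix(features: list[ContigFeatures]) -> np.ndarray:
    # Log features are concatenated on their natural scales (PCA centers).
    # Per-dimension z-scoring is deliberately NOT applied: it inflates the
    # 136 composition dimensions to unit variance even when they carry pure
    # sampling noise, which drowns a single coverage dimension and makes
    # coverage-only separation impossible.  On the log scale the variances
    # are already informative (noise dims stay small).
    comp = np.stack([f.composition for f in features])
    cov = np.stack([f.coverage for f in features])
    return np.hstack([comp, cov])


def fit_clusters(features: list[ContigFeatures], K: int, seed: int = 0,
                 n_init: int = 10, variance_retained: float = 0.9) -> ClusterAssignment:
    """Cluster featurized contigs into exactly K groups.

    PCA keeps the leading components explaining ``variance_retained`` of the
    variance; the Gaussian mixture (diagonal covariance) is restarted
    ``n_init`` times from the given seed and the best model by training
    log-likelihood is kept.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = len(features)
    if n < K:
        raise ValueError(
            f"only {n} contigs for K={K} clusters; lower K (e.g. override the "
            f"species count) or supply more contigs"
        )
    X = _feature_matrix(features)
    max_comp = min(n, X.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full", random_state=seed)
    Z = pca.fit_transform(X)
    ratios = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(ratios, variance_retained) + 1)
    keep = min(max(keep, 1), Z.shape[1])
    Z = Z[:, :keep]

    gmm = GaussianMixture(n_components=K, covariance_type="diag",
                          n_init=n_init, random_state=seed,
                          reg_covar=1e-4, max_iter=500)
    gmm.fit(Z)
    resp = gmm.predict_proba(Z)
    labels = np.argmax(resp, axis=1)  # argmax takes the lowest index on ties

    ids = [f.contig_id for f in features]
    return ClusterAssignment(
        K=K,
        labels=dict(zip(ids, (int(l) for l in labels))),
        responsibilities=pd.DataFrame(resp, index=ids, columns=range(K)),
        seed=seed,
    )


def cluster_report(assignment: ClusterAssignment,
                   contigs: ContigSet) -> pd.DataFrame:
    """Per-cluster contig counts and total bases (empty clusters included)."""
    lengths = {c.contig_id: len(c) for c in contigs}
    rows = []
    for k in range(assignment.K):
        members = assignment.members(k)
        rows.append({
            "cluster_id": k,
            "n_contigs": len(members),
            "total_bases": sum(lengths.get(cid, 0) for cid in members),
        })
    return pd.DataFrame(rows)
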