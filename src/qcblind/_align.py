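"""Seed-and-extend ungapped local alignment with an e-value style significance.

Used for marker-vs-contig search, read-vs-rRNA species counting, and
contig-vs-reference placement.  Seeds are exact ``seed_len``-mers; each seed
is extended without gaps in both directions with an x-drop rule (stop once
the running score falls ``xdrop`` below the best seen).  Significance of a
hit of score S against a database of n total bases, for a query of m bases,
follows the Karlin-Altschul form

    E = K * m * n * exp(-lambda * S)

with lambda solved from sum_i p_i p_j exp(lambda * s_ij) = 1 under uniform
base composition, and K fixed at 0.621 (the standard ungapped nucleotide
value for match +1 / mismatch -2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from ._kmers import encode, revcomp, window_codes

K_PARAM = 0.621


@lru_cache(maxsize=None)
def karlin_altschul_lambda(match: int = 1, mismatch: int = -2) -> float:
    """Solve (1/4) e^(lambda*match) + (3/4) e^(lambda*mismatch) = 1, lambda > 0."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


def evalue(score: float, query_len: int, db_len: int,
           match: int = 1, mismatch: int = -2) -> float:
    lam = karlin_altschul_lambda(match, mismatch)
    # guard exp underflow for very high scores
    exponent = -lam * score
    if exponent < -700:
        return 0.0
    return K_PARAM * query_len * db_len * math.exp(exponent)


@dataclass
class LocalHit:
    query_id: str
    subject_id: str
    strand: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int
    matches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


class SeedIndex:
    """Exact-seed lookup table over a set of subject sequences."""

    def __init__(self, subjects: list[tuple[str, str]], seed_len: int):
        self.subjects = subjects
        self.seed_len = seed_len
        self.total_bases = sum(len(s) for _, s in subjects)
        index: dict[int, list[tuple[int, int]]] = {}
        for si, (_, seq) in enumerate(subjects):
            codes, valid = window_codes(encode(seq), seed_len)
            clist = codes.tolist()
            vlist = valid.tolist()
            for pos in range(len(clist)):
                if vlist[pos]:
                    index.setdefault(clist[pos], []).append((si, pos))
        self._index = index

    def get(self, code: int) -> list[tuple[int, int]]:
        return self._index.get(code, [])


def _extend(q: str, s: str, i: int, j: int, seed_len: int,
            match: int, mismatch: int, xdrop: int):
    score = seed_len * match
    matches = seed_len
    # right of the seed
    best, best_m, best_e = score, matches, 0
    cur, cur_m = score, matches
    e = 0
    qn, sn = len(q), len(s)
    while i + seed_len + e < qn and j + seed_len + e < sn:
        if q[i + seed_len + e] == s[j + seed_len + e]:
            cur += match
            cur_m += 1
        else:
            cur += mismatch
        e += 1
        if cur > best:
            best, best_m, best_e = cur, cur_m, e
        if cur <= best - xdrop:
            break
    score, matches, right = best, best_m, best_e
    # left of the seed
    best, best_m, best_f = score, matches, 0
    cur, cur_m = score, matches
    f = 0
    while i - f - 1 >= 0 and j - f - 1 >= 0:
        if q[i - f - 1] == s[j - f - 1]:
            cur += match
            cur_m += 1
        else:
            cur += mismatch
        f += 1
        if cur > best:
            best, best_m, best_f = cur, cur_m, f
        if cur <= best - xdrop:
            break
    score, matches, left = best, best_m, best_f
    return i - left, i + seed_len + right, j - left, j + seed_len + right, score, matches


def seed_extend_search(queries: list[tuple[str, str]],
                       index: SeedIndex,
                       step: int = 1,
                       match: int = 1,
                       mismatch: int = -2,
                       xdrop: int = 20,
                       both_strands: bool = True) -> list[LocalHit]:
    """All x-drop extensions of exact seed matches, deduplicated by diagonal.

    Query coordinates of minus-strand hits refer to the reverse-complemented
    query.  One extension is reported per (subject, strand, diagonal).
    """
    k = index.seed_len
    hits: list[LocalHit] = []
    for qid, qseq in queries:
        seen: set[tuple[int, str, int]] = set()
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            q = qseq if strand == "+" else revcomp(qseq)
            if len(q) < k:
                continue
            codes, valid = window_codes(encode(q), k)
            clist = codes.tolist()
            vlist = valid.tolist()
            for i in range(0, len(clist), step):
                if not vlist[i]:
                    continue
                for si, pos in index.get(clist[i]):
                    key = (si, strand, pos - i)
                    if key in seen:
                        continue
                    seen.add(key)
                    sid, sseq = index.subjects[si]
                    qs, qe, ss, se, score, m = _extend(
                        q, sseq, i, pos, k, match, mismatch, xdrop
                    )
                    hits.append(LocalHit(qid, sid, strand, qs, qe, ss, se, score, m))
    return hits


def best_hit_per_query(hits: list[LocalHit]) -> dict[str, LocalHit]:
    """Highest-scoring hit per query; ties broken by subject id, then position."""
    best: dict[str, LocalHit] = {}
    for h in hits:
        b = best.get(h.query_id)
        if (b is None or h.score > b.score
                or (h.score == b.score and (h.subject_id, h.s_start) < (b.subject_id, b.s_start))):
            best[h.query_id] = h
    return best
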