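"""Vectorized 2-bit k-mer encoding shared by the assembler, mapper and aligners.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, separators) is 255
and invalidates every window that contains it.  A k-mer of length k <= 31 is
packed big-endian into a uint64 (first base in the highest occupied bits), so
lexicographic order on strings equals numeric order on codes.
"""

from __future__ import annotations

import numpy as np

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.array(list("ACGT"))

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# rc of a 16-bit word holding 8 packed bases: complement each base, reverse order
_j = np.arange(65536, dtype=np.uint64)
_RC16 = np.zeros(65536, dtype=np.uint64)
for _p in range(8):
    _base = (_j >> np.uint64(2 * (7 - _p))) & np.uint64(3)
    _RC16 |= (np.uint64(3) - _base) << np.uint64(2 * _p)
del _j, _base


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array (0..3, 255 for non-ACGT)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_kmer(kmer: str) -> int | None:
    """Pack a single k-mer (k <= 31) into an int; None if it contains non-ACGT."""
    code = 0
    for ch in kmer:
        v = _ENC[ord(ch)]
        if v > 3:
            return None
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement of a packed k-mer code (k <= 31), via 16-bit chunks."""
    r = 0
    for i in range(4):
        r = (r << 16) | int(_RC16[(code >> (16 * i)) & 0xFFFF])
    return r >> (2 * (32 - k))


def canonical_code(code: int, k: int) -> int:
    return min(code, revcomp_code(code, k))


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mer codes."""
    c = codes.astype(np.uint64, copy=False)
    m16 = np.uint64(0xFFFF)
    r = _RC16[(c & m16).astype(np.int64)]
    for i in (1, 2, 3):
        r = (r << np.uint64(16)) | _RC16[((c >> np.uint64(16 * i)) & m16).astype(np.int64)]
    return r >> np.uint64(2 * (32 - k))


def window_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all length-k windows of an encoded array.

    Returns ``(codes, valid)`` where ``codes`` has ``n - k + 1`` uint64 entries
    and ``valid`` flags windows free of non-ACGT bases.  Built by combining
    power-of-two sub-window codes, so the whole pass is vectorized.
    """
    n = int(vals.size)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = (vals > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0

    v = (vals & 3).astype(np.uint64)
    arrs = [v]
    lens = [1]
    while lens[-1] * 2 <= k:
        a, m = arrs[-1], lens[-1]
        arrs.append((a[: a.size - m] << np.uint64(2 * m)) | a[m:])
        lens.append(2 * m)

    res: np.ndarray | None = None
    reslen = 0
    for a, m in zip(reversed(arrs), reversed(lens)):
        if reslen + m > k:
            continue
        if res is None:
            res, reslen = a, m
        else:
            cnt = n - reslen - m + 1
            res = (res[:cnt] << np.uint64(2 * m)) | a[reslen : reslen + cnt]
            reslen += m
    assert res is not None and reslen == k
    return res, valid


def canonical_window_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of forward/reverse-complement) codes of all k-windows."""
    fwd, valid = window_codes(vals, k)
    return np.minimum(fwd, revcomp_codes(fwd, k)), valid
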