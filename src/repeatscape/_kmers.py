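"""Canonical k-mer encoding shared by the organelle filter and read clustering.

K-mers are packed into uint64 (2 bits/base, so k <= 31). The canonical form of
a k-mer is the lexicographic minimum of the k-mer and its reverse complement,
which makes membership queries strand-independent.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_CODE[_b] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes; anything outside ACGT becomes 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """All canonical k-mer codes of ``seq`` (windows containing non-ACGT are dropped).

    Returns a uint64 array of length ``max(0, len(seq) - k + 1)`` minus invalid
    windows, in sequence order.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    if len(seq) < k:
        return np.empty(0, dtype=np.uint64)
    codes = encode_bases(seq)
    windows = sliding_window_view(codes, k)
    valid = (windows != 255).all(axis=1)
    win = windows[valid].astype(np.uint64)
    if win.size == 0:
        return np.empty(0, dtype=np.uint64)
    pow_fwd = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pow_rev = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    fwd = win @ pow_fwd
    rev = (np.uint64(3) - win) @ pow_rev
    return np.minimum(fwd, rev)


def kmer_set(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mers of ``seq`` — the read's k-mer profile."""
    return np.unique(canonical_kmers(seq, k))


def shared_fraction(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of shared canonical k-mers relative to the smaller profile.

    ``a`` and ``b`` must be sorted unique arrays as returned by :func:`kmer_set`.
    """
    denom = min(a.size, b.size)
    if denom == 0:
        return 0.0
    shared = np.intersect1d(a, b, assume_unique=True).size
    return shared / denom
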