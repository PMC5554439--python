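"""Integer k-mer machinery shared by anchoring, read placement and repeat detection.

Sequences are encoded as uint8 arrays (A,C,G,T -> 0..3, anything else -> 4).
A k-mer is packed into a single int64 in base 4, which is collision-free for
k <= 26; windows containing a non-ACGT base get code -1 and never match.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

MAX_K = 26  # 4**26 < 2**63


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string as an int64 array of base codes."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 becomes N)."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of every k-mer of an encoded sequence (-1 for invalid windows)."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    codes = win @ weights
    bad = np.convolve((enc == 4).astype(np.int64), np.ones(k, dtype=np.int64), mode="valid") > 0
    codes[bad] = -1
    return codes


def unique_kmer_positions(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sorted codes, start positions) of k-mers occurring exactly once."""
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    neq = sc[1:] != sc[:-1]
    first = np.r_[True, neq]
    last = np.r_[neq, True]
    keep = first & last & (sc >= 0)
    return sc[keep], order[keep]


def kmer_index(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (codes, positions) over all valid k-mers, for searchsorted lookups."""
    valid = codes >= 0
    pos = np.flatnonzero(valid)
    vals = codes[pos]
    order = np.argsort(vals, kind="stable")
    return vals[order], pos[order]


def lookup(index: tuple[np.ndarray, np.ndarray], code: int) -> np.ndarray:
    """Positions at which ``code`` occurs, from a :func:`kmer_index`."""
    vals, pos = index
    lo = np.searchsorted(vals, code, side="left")
    hi = np.searchsorted(vals, code, side="right")
    return pos[lo:hi]
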