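"""Coverage-threshold deletion breakpoints within a reference island.

Reads of each genome are placed on the extracted island sequence with a
purpose-built exact/near-exact seeded placer (adequate for synthetic,
error-light reads; not a general aligner). Depth is median-filtered, then
maximal runs where depth drops below the threshold (default 10x, strictly
less) become (drop, recover) breakpoint pairs; genomes sharing breakpoint
pair lists within a tolerance share a deletion-pattern label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter

from ._kmer import encode, kmer_codes
from .simulate import ReadSet

DEFAULT_THRESHOLD = 10  # x; depth strictly below marks absence
DEFAULT_MIN_SPAN = 200  # bp; shorter sub-threshold runs are ignored
MAX_MISMATCHES = 3
SEED_K = 20


@dataclass
class CoverageVector:
    island_id: str
    genome: str
    depth: np.ndarray  # per-base read depth over the island

    def mean(self) -> float:
        return float(self.depth.mean())


@dataclass
class DeletionCall:
    genome: str
    pairs: tuple[tuple[int, int], ...]  # (drop, recover) coordinates, sorted
    pattern: str | None = None


def compute_coverage(
    reads: ReadSet,
    island_reference: str,
    island_id: str = "island",
    max_mismatches: int = MAX_MISMATCHES,
) -> CoverageVector:
    """Depth of best-placed reads over the island reference.

    Each read is seeded by exact k-mers at a few offsets and placed at the
    locus with the fewest mismatches (<= max_mismatches, full read within
    the island); unplaced reads are ignored.
    """
    if reads.n_reads == 0 or not island_reference:
        raise ValueError("reads and island reference must be non-empty")
    L = len(island_reference)
    ref = encode(island_reference)
    codes = kmer_codes(ref, SEED_K)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]

    matrix = reads.matrix
    rl = reads.read_length
    offsets = [o for o in (0, rl // 2, rl - SEED_K) if 0 <= o <= rl - SEED_K]
    weights = 4 ** np.arange(SEED_K - 1, -1, -1, dtype=np.int64)

    starts = np.full(matrix.shape[0], -1, dtype=np.int64)
    unplaced = np.arange(matrix.shape[0])
    diff = np.zeros(L + 1, dtype=np.int64)
    for off in offsets:
        if unplaced.size == 0:
            break
        sub = matrix[unplaced, off : off + SEED_K]
        read_codes = sub @ weights
        read_codes[(sub > 3).any(axis=1)] = -1
        lo = np.searchsorted(sorted_codes, read_codes, side="left")
        hi = np.searchsorted(sorted_codes, read_codes, side="right")
        still = []
        for idx, l, h, code in zip(unplaced, lo, hi, read_codes):
            placed = False
            if code >= 0 and h > l:
                best_mm, best_pos = max_mismatches + 1, -1
                for cand in order[l:h]:
                    pos = int(cand) - off
                    if pos < 0 or pos + rl > L:
                        continue
                    mm = int(np.count_nonzero(matrix[idx] != ref[pos : pos + rl]))
                    if mm < best_mm:
                        best_mm, best_pos = mm, pos
                if best_pos >= 0 and best_mm <= max_mismatches:
                    starts[idx] = best_pos
                    diff[best_pos] += 1
                    diff[best_pos + rl] -= 1
                    placed = True
            if not placed:
                still.append(idx)
        unplaced = np.array(still, dtype=np.int64)
    depth = np.cumsum(diff[:-1])
    return CoverageVector(island_id, reads.genome_id, depth)


def call_breakpoints(
    coverage: CoverageVector,
    threshold: float = DEFAULT_THRESHOLD,
    smooth_window: int = 200,
    min_span: int = DEFAULT_MIN_SPAN,
) -> DeletionCall:
    """Maximal sub-threshold runs of (median-smoothed) depth as breakpoint pairs.

    Depth exactly at the threshold is *not* a deletion; strictly below is.
    Whole-island absence comes out as a single full-length pair.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    depth = coverage.depth.astype(float)
    if smooth_window > 1:
        depth = median_filter(depth, size=smooth_window, mode="nearest")
    below = depth < threshold
    bounds = np.flatnonzero(np.diff(np.r_[False, below, False].astype(np.int8)))
    pairs = [
        (int(s), int(e))
        for s, e in zip(bounds[::2], bounds[1::2])
        if e - s >= min_span
    ]
    return DeletionCall(coverage.genome, tuple(pairs))


def group_patterns(
    calls: Sequence[DeletionCall],
    tolerance: int = 250,
) -> dict[str, DeletionCall]:
    """Group genomes whose breakpoint pair lists agree within tolerance.

    Labels are assigned A, B, C... by descending group size, then by
    leftmost breakpoint coordinate (the intact group sorts first among
    ties). Returns genome -> labelled call.
    """

    def matches(a: DeletionCall, b: DeletionCall) -> bool:
        if len(a.pairs) != len(b.pairs):
            return False
        return all(
            abs(s1 - s2) <= tolerance and abs(e1 - e2) <= tolerance
            for (s1, e1), (s2, e2) in zip(a.pairs, b.pairs)
        )

    groups: list[list[DeletionCall]] = []
    for call in sorted(calls, key=lambda c: (len(c.pairs), c.pairs, c.genome)):
        for group in groups:
            if matches(group[0], call):
                group.append(call)
                break
        else:
            groups.append([call])
    ordered = sorted(
        groups, key=lambda g: (-len(g), g[0].pairs[0][0] if g[0].pairs else -1)
    )
    out: dict[str, DeletionCall] = {}
    for i, group in enumerate(ordered):
        label = chr(ord("A") + i)
        for call in group:
            out[call.genome] = DeletionCall(call.genome, call.pairs, label)
    return out
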