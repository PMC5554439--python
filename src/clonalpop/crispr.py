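"""CRISPR array detection and spacer matching.

Arrays are found by a k-mer-seeded tandem-repeat scan with CRT-like
constraints (>= 3 repeat copies, repeat 19-38 bp, spacer 19-48 bp); spacer
matching is a word-seeded (default word size 7) ungapped local alignment
scored +2/-3, with e-values from Karlin-Altschul statistics whose (lambda,
K) are solved numerically for the score system under uniform base
composition — calibrated like an ungapped BLASTN with dust filtering off,
not bit-identical to any particular BLAST build.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from ._kmer import encode, kmer_codes, kmer_index, lookup, revcomp

MIN_REPEATS = 3
REPEAT_RANGE = (19, 38)
SPACER_RANGE = (19, 48)
SEED_K = 16
WORD_SIZE = 7
MATCH, MISMATCH = 2, -3
E_CUTOFF = 1e-3


@dataclass
class CrisprArray:
    genome: str
    start: int
    end: int
    repeat: str
    spacers: tuple[str, ...]
    spacer_coords: tuple[tuple[int, int], ...]

    @property
    def n_repeats(self) -> int:
        return len(self.spacers) + 1


@dataclass(frozen=True)
class SpacerMatch:
    query: str
    subject: str
    strand: str
    score: int
    evalue: float
    identity: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]


@dataclass(frozen=True)
class SelfTarget:
    genome: str
    match: SpacerMatch
    annotation: str  # overlapping feature label, or "unannotated"


# ---------------------------------------------------------------------------
# array detection
# ---------------------------------------------------------------------------


def detect_arrays(
    sequence: str,
    genome: str = "genome",
    min_repeats: int = MIN_REPEATS,
    repeat_range: tuple[int, int] = REPEAT_RANGE,
    spacer_range: tuple[int, int] = SPACER_RANGE,
) -> list[CrisprArray]:
    """Find CRISPR arrays as regularly recurring exact k-mers.

    Candidate seeds are k-mers (k=16) occurring >= min_repeats times with
    successive spacings inside the repeat+spacer period window; each run is
    extended to the maximal common repeat across all copies and validated
    against the repeat/spacer length constraints.
    """
    if not sequence:
        raise ValueError("empty sequence")
    enc = encode(sequence)
    codes = kmer_codes(enc, SEED_K)
    valid = codes >= 0
    vals = codes[valid]
    pos = np.flatnonzero(valid)
    uniq, inverse, counts = np.unique(vals, return_inverse=True, return_counts=True)
    cand = np.flatnonzero((counts >= min_repeats) & (counts <= 200))
    if cand.size == 0:
        return []
    period_lo = repeat_range[0] + spacer_range[0]
    period_hi = repeat_range[1] + spacer_range[1]

    order = np.argsort(inverse, kind="stable")
    boundaries = np.searchsorted(inverse[order], cand, side="left")
    boundaries_hi = np.searchsorted(inverse[order], cand, side="right")

    claimed: list[tuple[int, int]] = []
    arrays: list[CrisprArray] = []
    candidate_runs: list[np.ndarray] = []
    for lo, hi in zip(boundaries, boundaries_hi):
        ps = np.sort(pos[order[lo:hi]])
        diffs = np.diff(ps)
        ok = (diffs >= period_lo) & (diffs <= period_hi)
        brk = np.flatnonzero(~ok)
        run_edges = np.r_[0, brk + 1, ps.size]
        for s, e in zip(run_edges[:-1], run_edges[1:]):
            if e - s >= min_repeats:
                candidate_runs.append(ps[s:e])
    # richest runs first: k-mers spanning a spacer/repeat junction can form
    # shorter competing runs when spacer ends coincide; the full-array run
    # must claim the locus before they do
    candidate_runs.sort(key=lambda r: (-r.size, int(r[0])))
    for ps in candidate_runs:
        if any(s <= p < e for p in ps for s, e in claimed):
            continue
        arr = _build_array(sequence, enc, ps, genome, repeat_range, spacer_range, min_repeats)
        if arr is not None and not any(arr.start < e and arr.end > s for s, e in claimed):
            arrays.append(arr)
            claimed.append((arr.start, arr.end))
    arrays.sort(key=lambda a: a.start)
    return arrays


def _build_array(seq, enc, ps, genome, repeat_range, spacer_range, min_repeats):
    k = SEED_K
    n = len(seq)
    # extend the exact seed left and right across all copies, maximally (an
    # over-long common repeat must be seen as such and rejected, not capped)
    hard_cap = 2 * repeat_range[1]
    left = 0
    while (
        left + k < hard_cap
        and ps[0] - left - 1 >= 0
        and len({seq[p - left - 1] for p in ps}) == 1
    ):
        left += 1
    right = 0
    while (
        left + k + right < hard_cap
        and ps[-1] + k + right < n
        and len({seq[p + k + right] for p in ps}) == 1
    ):
        right += 1
    rlen = left + k + right
    if not repeat_range[0] <= rlen <= repeat_range[1]:
        return None
    starts = [int(p) - left for p in ps]
    # validate spacers; trim to the maximal valid run
    runs: list[list[int]] = [[starts[0]]]
    for a, b in zip(starts, starts[1:]):
        gap = b - (a + rlen)
        if spacer_range[0] <= gap <= spacer_range[1]:
            runs[-1].append(b)
        else:
            runs.append([b])
    best = max(runs, key=len)
    if len(best) < min_repeats:
        return None
    spacers = []
    coords = []
    for a, b in zip(best, best[1:]):
        coords.append((a + rlen, b))
        spacers.append(seq[a + rlen : b])
    repeat = seq[best[0] : best[0] + rlen]
    return CrisprArray(
        genome, best[0], best[-1] + rlen, repeat, tuple(spacers), tuple(coords)
    )


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics for the ungapped score system
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def karlin_altschul_params(
    match: int = MATCH, mismatch: int = MISMATCH, p_match: float = 0.25
) -> tuple[float, float, float]:
    """(lambda, K, H) for i.i.d. scores {match w.p. p, mismatch w.p. 1-p}.

    lambda is the positive root of E[exp(lambda*S)] = 1; H is the relative
    entropy of the aligned-pair distribution; K follows Karlin & Altschul's
    lattice-case formula with sigma evaluated by convolving the score
    distribution.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need a positive match score and negative mismatch score")
    if p_match * match + (1 - p_match) * mismatch >= 0:
        raise ValueError("expected score must be negative")

    def mgf_minus_one(lam):
        return p_match * math.exp(lam * match) + (1 - p_match) * math.exp(lam * mismatch) - 1

    lam = brentq(mgf_minus_one, 1e-9, 20.0)
    H = lam * (
        p_match * match * math.exp(lam * match)
        + (1 - p_match) * mismatch * math.exp(lam * mismatch)
    )
    d = math.gcd(match, -mismatch)

    # sigma = sum_j (1/j) [ P(S_j >= 0) + E(e^{lam S_j}; S_j < 0) ]
    span = match - mismatch
    pmf = np.zeros(span + 1)
    pmf[0] = 1 - p_match  # score == mismatch
    pmf[span] = p_match  # score == match
    sigma = 0.0
    conv = np.array([1.0])
    offset = 0  # conv[i] = P(S_j = mismatch*j + i)
    for j in range(1, 200):
        conv = np.convolve(conv, pmf)
        offset = mismatch * j
        scores = offset + np.arange(conv.size)
        neg = scores < 0
        term = conv[~neg].sum() + float(np.sum(conv[neg] * np.exp(lam * scores[neg])))
        sigma += term / j
        if term / j < 1e-12:
            break
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return lam, K, H


def evalue(score: int, m: int, n: int, match: int = MATCH, mismatch: int = MISMATCH) -> float:
    lam, K, _ = karlin_altschul_params(match, mismatch)
    return K * m * n * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# spacer matching
# ---------------------------------------------------------------------------


def match_spacers(
    queries: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    e_cutoff: float = E_CUTOFF,
    word_size: int = WORD_SIZE,
    both_strands: bool = True,
    exclude_self: bool = True,
) -> list[SpacerMatch]:
    """Word-seeded ungapped local matches with E <= cutoff.

    ``queries`` and ``subjects`` are (id, sequence) pairs; subjects may be
    spacers or whole genomes. For each (query, subject) pair the best
    non-overlapping hits per strand are reported. ``exclude_self`` skips
    identical (query id == subject id) comparisons in all-vs-all mode.
    """
    if not queries:
        raise ValueError("empty query set")
    out: list[SpacerMatch] = []
    for sid, sseq in subjects:
        senc = encode(sseq)
        index = kmer_index(kmer_codes(senc, word_size))
        for qid, qseq in queries:
            if exclude_self and qid == sid:
                continue
            for strand in ("+", "-") if both_strands else ("+",):
                q = qseq if strand == "+" else revcomp(qseq)
                hits = _search_one(q, senc, index, word_size)
                for score, qs, qe, ss, se, ident in hits:
                    E = evalue(score, len(qseq), len(sseq))
                    if E <= e_cutoff:
                        if strand == "-":
                            qs, qe = len(qseq) - qe, len(qseq) - qs
                        out.append(
                            SpacerMatch(qid, sid, strand, score, E, ident, (qs, qe), (ss, se))
                        )
    out.sort(key=lambda h: (h.query, h.subject, h.evalue))
    return out


def _search_one(query: str, senc: np.ndarray, index, word_size: int):
    qenc = encode(query)
    qcodes = kmer_codes(qenc, word_size)
    best_by_diag: dict[int, tuple] = {}
    for qi, code in enumerate(qcodes):
        if code < 0:
            continue
        for si in lookup(index, int(code)):
            diag = int(si) - qi
            known = best_by_diag.get(diag)
            if known is not None and known[1] <= qi < known[2]:
                continue  # seed inside an already-extended hit on this diagonal
            hit = _extend(qenc, senc, qi, int(si), word_size)
            if known is None or hit[0] > known[0]:
                best_by_diag[diag] = hit
    # non-overlapping best hits by subject interval
    hits = sorted(best_by_diag.values(), key=lambda h: -h[0])
    chosen: list[tuple] = []
    for h in hits:
        if all(h[4] <= c[3] or h[3] >= c[4] for c in chosen):
            chosen.append(h)
    return chosen


def _extend(qenc, senc, qi, si, word_size):
    score = MATCH * word_size
    # right
    best_r, run = 0, 0
    t = 0
    while qi + word_size + t < qenc.size and si + word_size + t < senc.size:
        run += MATCH if qenc[qi + word_size + t] == senc[si + word_size + t] else MISMATCH
        t += 1
        if run > best_r:
            best_r, ext_r = run, t
    ext_r = 0 if best_r == 0 else ext_r
    # left
    best_l, run = 0, 0
    t = 0
    while qi - 1 - t >= 0 and si - 1 - t >= 0:
        run += MATCH if qenc[qi - 1 - t] == senc[si - 1 - t] else MISMATCH
        t += 1
        if run > best_l:
            best_l, ext_l = run, t
    ext_l = 0 if best_l == 0 else ext_l
    score += best_r + best_l
    qs, qe = qi - ext_l, qi + word_size + ext_r
    ss, se = si - ext_l, si + word_size + ext_r
    matches = int(np.count_nonzero(qenc[qs:qe] == senc[ss:se]))
    identity = matches / (qe - qs)
    return (score, qs, qe, ss, se, identity)


# ---------------------------------------------------------------------------
# self-targets
# ---------------------------------------------------------------------------


def find_self_targets(
    arrays_by_genome: dict[str, Sequence[CrisprArray]],
    genomes: Sequence[tuple[str, str]],
    features: dict[str, Sequence[tuple[int, int, str]]] | None = None,
    e_cutoff: float = E_CUTOFF,
) -> list[SelfTarget]:
    """Spacer hits outside every detected array: potential self-targeting loci.

    ``features`` optionally maps genome id -> (start, end, label) intervals
    (islands, integrated elements) used to annotate each self-target.
    """
    out: list[SelfTarget] = []
    for gid, gseq in genomes:
        arrays = arrays_by_genome.get(gid, [])
        spacer_queries = [
            (f"{gid}:array{ai}:spacer{si}", s)
            for ai, arr in enumerate(arrays)
            for si, s in enumerate(arr.spacers)
        ]
        if not spacer_queries:
            continue
        matches = match_spacers(
            spacer_queries, [(gid, gseq)], e_cutoff=e_cutoff, exclude_self=False
        )
        array_intervals = [(a.start, a.end) for a in arrays]
        for m in matches:
            s, e = m.subject_interval
            if any(s < ae and e > as_ for as_, ae in array_intervals):
                continue
            label = "unannotated"
            for fs, fe, flabel in (features or {}).get(gid, ()):
                if s < fe and e > fs:
                    label = flabel
                    break
            out.append(SelfTarget(gid, m, label))
    return out


def conservation_matrix(arrays_by_genome: dict[str, Sequence[CrisprArray]]):
    """Spacer content per genome: genome -> tuple of per-array spacer tuples."""
    return {
        g: tuple(tuple(a.spacers) for a in arrays)
        for g, arrays in arrays_by_genome.items()
    }
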