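"""Anchored comparison of near-identical assemblies against a reference.

Replaces a whole-genome aligner for the near-clonal case: maximal exact
matches that are unique in both sequences are chained into the best
collinear subset (weighted longest-increasing-subsequence on reference
order); small inter-anchor gaps are resolved into SNP / insertion /
deletion / substitution calls by pairwise alignment, large gaps are left
for the variable-genome (island) stage; the intersection of per-genome
covered intervals yields core collinear blocks, and per-genome SNP calls
are assembled into the core SNP matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from ._kmer import encode, kmer_codes, unique_kmer_positions

SMALL_VARIANT_CAP = 50  # bp; gaps larger on either side are not small variants
MIN_CORE_BLOCK = 500  # bp; blocks must be strictly longer to count as core
SCAFFOLD_SPACER = 100  # 'N's between concatenated scaffolds; can never anchor


@dataclass(frozen=True)
class Anchor:
    """An exact-match interval unique in both sequences (0-based half-open)."""

    ref_start: int
    ref_end: int
    query_start: int
    query_end: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class AnchorChain:
    """Collinear chain of anchors for one (reference, query) pair."""

    genome: str
    anchors: list[Anchor]
    ref_length: int
    query_length: int

    def gaps(self) -> list[tuple[int, int, int, int]]:
        """Inter-anchor gaps as (ref_start, ref_end, query_start, query_end)."""
        out = []
        for a, b in zip(self.anchors, self.anchors[1:]):
            out.append((a.ref_end, b.ref_start, a.query_end, b.query_start))
        return out

    def covered_intervals(self, max_small: int = SMALL_VARIANT_CAP) -> list[tuple[int, int]]:
        """Reference intervals aligned to the query.

        Anchors joined across gaps that are small (<= max_small on both
        sides), i.e. across small-variant sites; split at larger gaps.
        """
        if not self.anchors:
            return []
        out = [[self.anchors[0].ref_start, self.anchors[0].ref_end]]
        for (rs, re, qs, qe), b in zip(self.gaps(), self.anchors[1:]):
            if re - rs <= max_small and qe - qs <= max_small and re - rs >= 0:
                out[-1][1] = b.ref_end
            else:
                out.append([b.ref_start, b.ref_end])
        return [(s, e) for s, e in out]

    def split_points(self, max_small: int = SMALL_VARIANT_CAP) -> list[int]:
        """Reference coordinates where a zero-width ref gap hides a large insertion."""
        return [
            rs
            for rs, re, qs, qe in self.gaps()
            if re - rs <= max_small and qe - qs > max_small
        ]

    def project(self, ref_pos: int) -> int | None:
        """Query coordinate of a reference position inside an anchor, else None."""
        for a in self.anchors:
            if a.ref_start <= ref_pos < a.ref_end:
                return a.query_start + (ref_pos - a.ref_start)
        return None


@dataclass(frozen=True)
class SmallVariant:
    """A small difference between one query genome and the reference."""

    genome: str
    position: int  # reference coordinate, 0-based
    type: str  # snp | insertion | deletion | substitution
    ref_allele: str
    alt_allele: str

    @property
    def length(self) -> int:
        if self.type == "insertion":
            return len(self.alt_allele)
        return len(self.ref_allele)

    def key(self) -> tuple:
        return (self.position, self.type, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class CoreBlock:
    """A reference interval collinearly present in every genome (> 500 bp)."""

    ref_start: int
    ref_end: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class SnpMatrix:
    """Genomes x polymorphic core sites, with the reference allele per site."""

    positions: np.ndarray  # (n_sites,) int, sorted
    ref_alleles: np.ndarray  # (n_sites,) '<U1'
    genomes: list[str]
    alleles: np.ndarray  # (n_genomes, n_sites) '<U1'

    @classmethod
    def from_alleles(cls, positions, ref_alleles, alleles_by_genome: dict[str, str]):
        genomes = list(alleles_by_genome)
        mat = np.array([list(alleles_by_genome[g]) for g in genomes], dtype="<U1")
        return cls(np.asarray(positions), np.asarray(ref_alleles, dtype="<U1"), genomes, mat)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def carriers(self, site: int) -> tuple[str, ...]:
        """Genomes whose allele differs from the reference at site index."""
        alt = self.alleles[:, site] != self.ref_alleles[site]
        return tuple(str(g) for g, a in zip(self.genomes, alt) if a)

    def row(self, genome: str) -> str:
        return "".join(self.alleles[self.genomes.index(genome)])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.alleles, index=self.genomes, columns=self.positions)
        df.loc["REF"] = self.ref_alleles
        df.index.name = "genome"
        return df.loc[["REF"] + self.genomes]


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def find_anchors(reference: str, query: str, min_match: int = 20, genome: str = "query") -> AnchorChain:
    """Chain unique maximal exact matches between reference and query.

    Matches are found as runs of shared k-mers (k = min_match) unique in
    both sequences, merged along matching diagonals, chained into the
    highest-total-length collinear subset, then adjacent chained anchors
    separated by identical sequence (a unique-k-mer dropout, e.g. inside a
    repeated CRISPR locus) are re-joined.
    """
    if not reference or not query:
        raise ValueError("empty sequence")
    if min_match < 15:
        raise ValueError("min_match must be >= 15")
    k = min_match
    rc, rp = unique_kmer_positions(kmer_codes(encode(reference), k))
    qc, qp = unique_kmer_positions(kmer_codes(encode(query), k))
    _, ri, qi = np.intersect1d(rc, qc, assume_unique=True, return_indices=True)
    rpos, qpos = rp[ri], qp[qi]
    if rpos.size == 0:
        return AnchorChain(genome, [], len(reference), len(query))
    order = np.argsort(rpos)
    rpos, qpos = rpos[order], qpos[order]

    # merge same-diagonal neighbours whose k-mers overlap or abut
    dr = np.diff(rpos)
    dq = np.diff(qpos)
    brk = np.r_[True, (dr != dq) | (dr > k) | (dr <= 0)]
    starts = np.flatnonzero(brk)
    ends = np.r_[starts[1:], rpos.size] - 1
    segs = [
        Anchor(int(rpos[s]), int(rpos[e]) + k, int(qpos[s]), int(qpos[e]) + k)
        for s, e in zip(starts, ends)
    ]

    chained = _chain_collinear(segs)
    merged = _merge_identical_gaps(chained, reference, query)
    return AnchorChain(genome, merged, len(reference), len(query))


CHAIN_OVERLAP_SLACK = 50  # bp; junction anchors may coincidentally overrun


def _chain_collinear(segs: list[Anchor]) -> list[Anchor]:
    """Weighted LIS over (ref, query) order; ties broken by smaller ref start.

    Anchors at deletion/insertion junctions can coincidentally extend a few
    bases past the true breakpoint, overlapping their neighbour; overlaps up
    to a small slack are allowed during chaining and trimmed afterwards.
    """
    m = len(segs)
    if m == 0:
        return []
    segs = sorted(segs, key=lambda a: (a.ref_start, a.query_start))
    best = [0.0] * m
    prev = [-1] * m
    for i, a in enumerate(segs):
        best[i] = float(a.length)
        for j in range(i):
            b = segs[j]
            if (
                b.ref_end <= a.ref_start + CHAIN_OVERLAP_SLACK
                and b.query_end <= a.query_start + CHAIN_OVERLAP_SLACK
                and b.ref_start < a.ref_start
                and b.query_start < a.query_start
            ):
                overlap = max(0, b.ref_end - a.ref_start, b.query_end - a.query_start)
                cand = best[j] + a.length - overlap
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    i = int(np.argmax(best))
    chain = []
    while i >= 0:
        chain.append(segs[i])
        i = prev[i]
    chain = chain[::-1]
    # trim overlaps: shift the later anchor's start (still an exact match)
    out: list[Anchor] = []
    for a in chain:
        if out:
            p = out[-1]
            t = max(0, p.ref_end - a.ref_start, p.query_end - a.query_start)
            if t >= a.length:
                continue
            if t > 0:
                a = Anchor(a.ref_start + t, a.ref_end, a.query_start + t, a.query_end)
        out.append(a)
    return out


def _merge_identical_gaps(anchors: list[Anchor], reference: str, query: str) -> list[Anchor]:
    if not anchors:
        return []
    out = [anchors[0]]
    for b in anchors[1:]:
        a = out[-1]
        rgap = reference[a.ref_end : b.ref_start]
        qgap = query[a.query_end : b.query_start]
        if len(rgap) == len(qgap) and rgap == qgap:
            out[-1] = Anchor(a.ref_start, b.ref_end, a.query_start, b.query_end)
        else:
            out.append(b)
    return out


def concat_scaffolds(scaffolds: Sequence[str]) -> str:
    """Join scaffolds with N spacers that can never anchor."""
    return ("N" * SCAFFOLD_SPACER).join(scaffolds)


# ---------------------------------------------------------------------------
# small-variant calling
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -3
_aligner.extend_gap_score = -1


def left_normalize(reference: str, position: int, ref_allele: str, alt_allele: str):
    """Shift an indel to its leftmost equivalent placement (canonical form)."""
    if ref_allele and alt_allele:  # substitution/snp: already canonical
        return position, ref_allele, alt_allele
    if ref_allele:  # deletion
        length = len(ref_allele)
        while position > 0 and reference[position - 1] == reference[position + length - 1]:
            position -= 1
        return position, reference[position : position + length], ""
    # insertion
    seq = alt_allele
    while position > 0 and seq and reference[position - 1] == seq[-1]:
        seq = reference[position - 1] + seq[:-1]
        position -= 1
    return position, "", seq


def call_small_variants(
    reference: str,
    query: str,
    chain: AnchorChain,
    max_small: int = SMALL_VARIANT_CAP,
) -> list[SmallVariant]:
    """Resolve small inter-anchor gaps into variant records.

    Gaps larger than ``max_small`` on either side are skipped here: they
    belong to the variable-genome stage (islands / element insertions /
    intermediate deletions), which reads them off the chain itself.
    """
    if chain.query_length != len(query) or chain.ref_length != len(reference):
        raise ValueError("chain does not match the given sequences")
    variants: list[SmallVariant] = []
    for rs, re, qs, qe in chain.gaps():
        rgap, qgap = re - rs, qe - qs
        if rgap < 0 or qgap < 0:
            raise ValueError("non-collinear chain")
        if rgap == 0 and qgap == 0:
            continue
        if rgap > max_small or qgap > max_small:
            continue
        variants.extend(
            _gap_to_variants(reference, rs, reference[rs:re], query[qs:qe], chain.genome)
        )
    return sorted(variants, key=lambda v: v.position)


def _gap_to_variants(reference, ref_start, rseq, qseq, genome) -> list[SmallVariant]:
    if not rseq:
        p, r, a = left_normalize(reference, ref_start, "", qseq)
        return [SmallVariant(genome, p, "insertion", r, a)]
    if not qseq:
        p, r, a = left_normalize(reference, ref_start, rseq, "")
        return [SmallVariant(genome, p, "deletion", r, a)]
    if len(rseq) == len(qseq):
        # equal-length gaps are positionally aligned: emit mismatch runs
        variants = []
        run = None
        for off in range(len(rseq) + 1):
            differs = off < len(rseq) and rseq[off] != qseq[off]
            if differs and run is None:
                run = off
            elif not differs and run is not None:
                vtype = "snp" if off - run == 1 else "substitution"
                variants.append(
                    SmallVariant(genome, ref_start + run, vtype, rseq[run:off], qseq[run:off])
                )
                run = None
        return variants
    aln = _aligner.align(rseq, qseq)[0]
    return _alignment_to_variants(reference, ref_start, rseq, qseq, aln, genome)


def _alignment_to_variants(reference, ref_start, rseq, qseq, aln, genome):
    # walk aligned blocks; collect mismatch runs and gap runs
    variants: list[SmallVariant] = []
    r_blocks, q_blocks = aln.aligned
    ri_prev, qi_prev = 0, 0
    events: list[tuple[str, int, str, str]] = []  # (kind, ref_off, ref_part, q_part)
    for (rs, re), (qs, qe) in zip(r_blocks, q_blocks):
        if rs > ri_prev and qs > qi_prev:
            events.append(("sub", ri_prev, rseq[ri_prev:rs], qseq[qi_prev:qs]))
        elif rs > ri_prev:
            events.append(("del", ri_prev, rseq[ri_prev:rs], ""))
        elif qs > qi_prev:
            events.append(("ins", ri_prev, "", qseq[qi_prev:qs]))
        # inside the matched block, emit mismatch runs
        run_start = None
        for off in range(re - rs):
            if rseq[rs + off] != qseq[qs + off]:
                if run_start is None:
                    run_start = off
            elif run_start is not None:
                events.append(
                    ("sub", rs + run_start, rseq[rs + run_start : rs + off], qseq[qs + run_start : qs + off])
                )
                run_start = None
        if run_start is not None:
            events.append(
                ("sub", rs + run_start, rseq[rs + run_start : re], qseq[qs + run_start : qe])
            )
        ri_prev, qi_prev = re, qe
    if len(rseq) > ri_prev and len(qseq) > qi_prev:
        events.append(("sub", ri_prev, rseq[ri_prev:], qseq[qi_prev:]))
    elif len(rseq) > ri_prev:
        events.append(("del", ri_prev, rseq[ri_prev:], ""))
    elif len(qseq) > qi_prev:
        events.append(("ins", ri_prev, "", qseq[qi_prev:]))

    for kind, off, rpart, qpart in events:
        pos = ref_start + off
        if kind == "sub":
            vtype = "snp" if len(rpart) == 1 else "substitution"
            variants.append(SmallVariant(genome, pos, vtype, rpart, qpart))
        elif kind == "del":
            p, r, a = left_normalize(reference, pos, rpart, "")
            variants.append(SmallVariant(genome, p, "deletion", r, a))
        else:
            p, r, a = left_normalize(reference, pos, "", qpart)
            variants.append(SmallVariant(genome, p, "insertion", r, a))
    return variants


def apply_variants(reference: str, variants: Iterable[SmallVariant]) -> str:
    """Apply one genome's variants to the reference (for round-trip checks)."""
    edits = []
    for v in variants:
        edits.append((v.position, len(v.ref_allele), v.alt_allele))
    edits.sort()
    out, prev = [], 0
    for p, rl, alt in edits:
        if p < prev:
            raise ValueError("overlapping variants")
        out.append(reference[prev:p])
        out.append(alt)
        prev = p + rl
    out.append(reference[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# core blocks and SNP matrix
# ---------------------------------------------------------------------------


def extract_core_blocks(
    chains: Sequence[AnchorChain],
    ref_length: int,
    min_block: int = MIN_CORE_BLOCK,
    max_small: int = SMALL_VARIANT_CAP,
) -> list[CoreBlock]:
    """Intersect per-genome covered intervals, split at gaps, filter > min_block."""
    if len(chains) < 2:
        raise ValueError("need at least 2 genomes")
    core = np.ones(ref_length, dtype=bool)
    splits: set[int] = set()
    for chain in chains:
        mask = np.zeros(ref_length, dtype=bool)
        for s, e in chain.covered_intervals(max_small):
            mask[s:e] = True
        core &= mask
        splits.update(chain.split_points(max_small))

    blocks: list[CoreBlock] = []
    bounds = np.flatnonzero(np.diff(np.r_[False, core, False].astype(np.int8)))
    for s, e in zip(bounds[::2], bounds[1::2]):
        cuts = sorted([p for p in splits if s < p < e])
        lo = int(s)
        for c in cuts + [int(e)]:
            if c - lo > min_block:
                blocks.append(CoreBlock(lo, c))
            lo = c
    return blocks


def build_snp_matrix(
    variants_by_genome: dict[str, Sequence[SmallVariant]],
    blocks: Sequence[CoreBlock],
    reference: str,
) -> SnpMatrix:
    """One column per reference position with a SNP record inside a core block."""
    starts = np.array([b.ref_start for b in blocks])
    ends = np.array([b.ref_end for b in blocks])

    def in_core(pos: int) -> bool:
        i = np.searchsorted(starts, pos, side="right") - 1
        return i >= 0 and pos < ends[i]

    genomes = list(variants_by_genome)
    site_alt: dict[int, dict[str, str]] = {}
    for g, variants in variants_by_genome.items():
        for v in variants:
            if v.type != "snp" or not in_core(v.position):
                continue
            prev = site_alt.setdefault(v.position, {}).get(g)
            if prev is not None and prev != v.alt_allele:
                raise ValueError(f"conflicting alleles for {g} at {v.position}")
            site_alt[v.position][g] = v.alt_allele
    positions = np.array(sorted(site_alt), dtype=int)
    ref_alleles = np.array([reference[p] for p in positions], dtype="<U1")
    mat = np.empty((len(genomes), positions.size), dtype="<U1")
    for i, g in enumerate(genomes):
        for j, p in enumerate(positions):
            mat[i, j] = site_alt[p].get(g, reference[p])
    return SnpMatrix(positions, ref_alleles, genomes, mat)
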