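"""Variable-genome detection: genomic islands and integrated elements.

An island is a maximal reference interval at least 1 kb long that is absent
from at least one genome; islands absent from only a single genome are
discarded (single-genome absences are overwhelmingly assembly artifacts in
real data), and surviving islands that are contiguous within a small gap
tolerance are grouped into larger variable regions. Integrated mobile
elements, which are absent from the reference and therefore can never be a
reference interval, are reported as element-backed variable regions whose
presence vectors come from the same presence-verification primitive used
to cross-check islands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kmer import encode, kmer_codes
from .core import AnchorChain

MIN_ISLAND = 1000  # bp
PRESENCE_MIN_COVERAGE = 0.5  # fraction of island anchored in the genome
PRESENCE_ANCHOR_K = 20


@dataclass
class AbsenceProfile:
    """Reference intervals (>= 1 kb) not covered by one genome's chain."""

    genome: str
    intervals: list[tuple[int, int]]


@dataclass
class GenomicIsland:
    """A maximal reference interval absent from >= 2 genomes (post-filter)."""

    start: int
    end: int
    absent: tuple[str, ...]  # genomes missing (part of) the interval
    realized: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start

    def presence(self, genomes: Sequence[str]) -> dict[str, bool]:
        absent = set(self.absent)
        return {g: g not in absent for g in genomes}


@dataclass
class VariableRegion:
    """Contiguous islands grouped together, or one integrated element."""

    region_id: str
    kind: str  # "island" | "element"
    islands: list[GenomicIsland]
    presence: dict[str, bool]
    span: tuple[int, int] | None  # reference interval; None for elements
    element_length: int = 0

    @property
    def length(self) -> int:
        if self.span is not None:
            return self.span[1] - self.span[0]
        return self.element_length


def build_absence_profiles(
    chains: Sequence[AnchorChain],
    ref_length: int,
    min_gap: int = MIN_ISLAND,
) -> list[AbsenceProfile]:
    """Per genome, reference intervals with no aligned coverage and size >= min_gap."""
    profiles = []
    for chain in chains:
        covered = chain.covered_intervals()
        gaps: list[tuple[int, int]] = []
        prev = 0
        for s, e in covered:
            if s - prev >= min_gap:
                gaps.append((prev, s))
            prev = max(prev, e)
        if ref_length - prev >= min_gap:
            gaps.append((prev, ref_length))
        profiles.append(AbsenceProfile(chain.genome, gaps))
    return profiles


def intermediate_deletions(
    chains: Sequence[AnchorChain],
    min_gap: int = 51,
    max_gap: int = MIN_ISLAND - 1,
) -> list[tuple[str, int, int]]:
    """Reference-side gaps of 51-999 bp: too big for small variants, too
    small for islands. Reported separately, excluded from both."""
    out = []
    for chain in chains:
        for rs, re, qs, qe in chain.gaps():
            if min_gap <= re - rs <= max_gap:
                out.append((chain.genome, rs, re))
    return out


def call_islands(
    profiles: Sequence[AbsenceProfile],
    min_len: int = MIN_ISLAND,
    gap_tolerance: int = 100,
    min_absent: int = 2,
) -> list[VariableRegion]:
    """Candidate islands -> single-genome filter -> contiguous grouping.

    A candidate island is a maximal reference interval absent from at least
    one genome (the union of overlapping per-genome absence intervals); a
    genome counts as absent if any of its absence intervals overlaps the
    island. Islands with fewer than ``min_absent`` absent genomes are
    dropped; survivors within ``gap_tolerance`` of each other merge into
    one variable region.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genomes")
    events: list[tuple[int, int, str]] = []
    for p in profiles:
        for s, e in p.intervals:
            events.append((s, e, p.genome))
    events.sort()
    # maximal union intervals
    candidates: list[list] = []  # [start, end, members]
    for s, e, g in events:
        if candidates and s <= candidates[-1][1]:
            candidates[-1][1] = max(candidates[-1][1], e)
            candidates[-1][2].append((s, e, g))
        else:
            candidates.append([s, e, [(s, e, g)]])

    islands: list[GenomicIsland] = []
    for start, end, members in candidates:
        if end - start < min_len:
            continue
        realized: dict[str, list[tuple[int, int]]] = {}
        for s, e, g in members:
            realized.setdefault(g, []).append((s, e))
        if len(realized) < min_absent:
            continue
        islands.append(
            GenomicIsland(
                start,
                end,
                tuple(sorted(realized)),
                {g: tuple(sorted(v)) for g, v in realized.items()},
            )
        )

    regions: list[VariableRegion] = []
    group: list[GenomicIsland] = []
    all_genomes = sorted({p.genome for p in profiles})

    def flush():
        if not group:
            return
        absent = sorted({g for isl in group for g in isl.absent})
        presence = {g: g not in absent for g in all_genomes}
        span = (group[0].start, group[-1].end)
        regions.append(
            VariableRegion(f"region{len(regions) + 1}", "island", list(group), presence, span)
        )
        group.clear()

    for isl in sorted(islands, key=lambda i: i.start):
        if group and isl.start - group[-1].end > gap_tolerance:
            flush()
        group.append(isl)
    flush()
    return regions


def genome_kmer_set(genome_sequence: str, k: int = PRESENCE_ANCHOR_K) -> np.ndarray:
    """Sorted unique k-mer codes of a genome (reusable across islands)."""
    return np.unique(kmer_codes(encode(genome_sequence), k))


def verify_presence(
    island_sequence: str,
    genome_sequence: str | None = None,
    min_coverage: float = PRESENCE_MIN_COVERAGE,
    k: int = PRESENCE_ANCHOR_K,
    genome_kmers: np.ndarray | None = None,
) -> tuple[bool, float]:
    """Is (a copy of) the island present in the genome?

    Coverage is the fraction of island positions covered by exact k-mers
    shared with the genome; present iff coverage >= min_coverage. Exact
    anchors subsume the >=95%-identity requirement on error-free
    assemblies. Pass ``genome_kmers`` (from :func:`genome_kmer_set`) to
    amortize the genome index across islands. Returns
    (present, coverage_fraction).
    """
    if len(island_sequence) < MIN_ISLAND:
        raise ValueError("island must be >= 1000 bp")
    if genome_kmers is None:
        if not genome_sequence:
            raise ValueError("empty genome")
        genome_kmers = genome_kmer_set(genome_sequence, k)
    icodes = kmer_codes(encode(island_sequence), k)
    idx = np.searchsorted(genome_kmers, icodes).clip(0, genome_kmers.size - 1)
    hit = (genome_kmers[idx] == icodes) & (icodes >= 0)
    # each hit k-mer covers positions [i, i+k); accumulate via a diff array
    diff = np.zeros(len(island_sequence) + k, dtype=np.int64)
    starts = np.flatnonzero(hit)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + k, -1)
    covered = np.cumsum(diff[: len(island_sequence)]) > 0
    frac = float(covered.mean())
    return frac >= min_coverage, frac


def element_regions(
    elements: Sequence[tuple[str, str]],
    genomes: Sequence[tuple[str, str]],
    min_coverage: float = PRESENCE_MIN_COVERAGE,
) -> list[VariableRegion]:
    """One variable region per integrated element, presence by verification."""
    regions = []
    kmer_sets = {gid: genome_kmer_set(gseq) for gid, gseq in genomes}
    for eid, eseq in elements:
        presence = {}
        for gid, _gseq in genomes:
            present, _ = verify_presence(eseq, genome_kmers=kmer_sets[gid], min_coverage=min_coverage)
            presence[gid] = present
        regions.append(VariableRegion(eid, "element", [], presence, None, len(eseq)))
    return regions


def variable_fraction(regions: Sequence[VariableRegion], ref_length: int) -> float:
    """Mean fraction of genome occupied by variable regions across genomes.

    For each genome, sums the spans of reference-backed regions plus the
    lengths of the elements it carries, over the reference length.
    """
    genomes = sorted({g for r in regions for g in r.presence})
    fracs = []
    for g in genomes:
        total = 0
        for r in regions:
            if r.kind == "island" and r.span is not None:
                total += r.span[1] - r.span[0]
            elif r.kind == "element" and r.presence.get(g):
                total += r.length
        fracs.append(total / ref_length)
    return float(np.mean(fracs)) if fracs else 0.0
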