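"""Synthetic clonal-population generator with full ground truth.

Emulates the statistical structure of a near-clonal archaeal population
sampled from two hot springs: a ~2 Mb-class reference (scaled down by
default), 47 genomes in 7 clades, sparse core SNPs partitioned into
clade-fixed / private / singleton alleles, small indels and multi-base
substitutions, one large genomic island carrying nested deletion patterns,
integrated plasmid- and virus-like elements, and identical CRISPR arrays.

Every planted feature is recorded in a :class:`TruthTable` whose coordinates
are 0-based, half-open, on the forward strand of the unedited reference, so
that each downstream analysis stage can be tested against ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from ._kmer import decode, encode, revcomp

logger = logging.getLogger(__name__)

MIN_EDIT_SPACING = 50  # bp between planted edits; keeps anchoring unambiguous

_SENSE_CODONS = None  # filled lazily from the genetic code


class Genome(NamedTuple):
    """A single assembled genome: an identifier and its forward-strand sequence."""

    id: str
    seq: str


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IslandSpec:
    """A reference interval subject to per-genome deletions.

    ``deletions`` maps genome id -> tuple of (start, end) pairs *relative to
    the island start*; genomes not listed keep the island intact.
    """

    start: int
    length: int
    deletions: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class InsertionSpec:
    """An integrated mobile element, absent from the reference."""

    element_id: str
    length: int
    position: int
    carriers: tuple[str, ...]


@dataclass(frozen=True)
class CrisprSpec:
    n_arrays: int = 4
    n_spacers: int = 8
    repeat_length: int = 24
    spacer_length: int = 38


@dataclass(frozen=True)
class ProtospacerPlant:
    """Copy one CRISPR spacer into a mobile element or island (a self-target)."""

    array: int
    spacer: int
    target: str  # element id, or "island<i>" for the i-th island spec
    offset: int  # offset of the copy within the target sequence


@dataclass
class PopulationConfig:
    """Parameters of one simulated population.

    Defaults reproduce the study conditions: 47 genomes in 7 clades on a
    500 kb reference, 119 core SNPs (19 clade-fixed + 17 private + 83
    singletons), 31 small indels (21 insertions, 10 deletions) plus 4
    multi-base substitutions, a 33 kb island with six nested deletion
    patterns, two plasmid-like and one virus-like integrated element, and
    four identical CRISPR arrays per genome.
    """

    reference_length: int = 500_000
    gc_fraction: float = 0.37
    n_genomes: int = 47
    clade_sizes: tuple[int, ...] = (6, 6, 5, 5, 5, 2, 18)
    fixed_snps_per_clade: tuple[int, ...] = (2, 2, 2, 2, 2, 3, 6)
    private_snps_per_clade: tuple[int, ...] = (3, 3, 3, 3, 2, 0, 3)
    singletons_per_genome: tuple[int, ...] | int = (
        # NG05 genomes (clades 1-5): 0-10 singletons each
        10, 6, 5, 5, 4, 4, 4, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0,
        # GG12 genomes (clades 6-7): 0-4 singletons each
        4, 2, 2, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
    )
    small_indels: int = 31
    small_substitutions: int = 4
    island_specs: tuple[IslandSpec, ...] | None = None  # None -> default layout
    insertion_specs: tuple[InsertionSpec, ...] | None = None
    crispr_spec: CrisprSpec = CrisprSpec()
    protospacer_plants: tuple[ProtospacerPlant, ...] | None = None
    gene_length: int = 900
    gene_spacing: int = 120
    plant_genes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.clade_sizes) != self.n_genomes:
            raise ValueError("clade_sizes must sum to n_genomes")
        for name in ("fixed_snps_per_clade", "private_snps_per_clade"):
            vec = getattr(self, name)
            if len(vec) != len(self.clade_sizes):
                raise ValueError(f"{name} must have one entry per clade")
            if any(v < 0 for v in vec):
                raise ValueError(f"{name} entries must be >= 0")
        for n_priv, size in zip(self.private_snps_per_clade, self.clade_sizes):
            if n_priv > 0 and size < 3:
                raise ValueError(
                    "private alleles need >=2 carriers forming a proper subset "
                    f"of a clade; impossible for a clade of size {size}"
                )
        if isinstance(self.singletons_per_genome, int):
            if self.singletons_per_genome < 0:
                raise ValueError("singletons_per_genome must be >= 0")
        elif len(self.singletons_per_genome) != self.n_genomes:
            raise ValueError("singletons_per_genome must have one entry per genome")
        if self.island_specs is None:
            self.island_specs = _default_islands(self)
        if self.insertion_specs is None:
            self.insertion_specs = _default_insertions(self)
        if self.protospacer_plants is None:
            self.protospacer_plants = _default_protospacers(self)
        _check_feature_layout(self)

    # -- derived bookkeeping -------------------------------------------------

    @property
    def genome_ids(self) -> list[str]:
        # the last clades take the second hot spring's prefix (two of them in
        # the full 7-clade layout, one in smaller layouts)
        n_clades = len(self.clade_sizes)
        n_gg_clades = 2 if n_clades >= 4 else (1 if n_clades >= 2 else 0)
        n_gg = sum(self.clade_sizes[n_clades - n_gg_clades :]) if n_gg_clades else 0
        n_ng = self.n_genomes - n_gg
        ids = [f"NG05_{i + 1:02d}" for i in range(n_ng)]
        ids += [f"GG12_{i + 1:02d}" for i in range(n_gg)]
        return ids

    @property
    def clade_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        ids = self.genome_ids
        i = 0
        for c, size in enumerate(self.clade_sizes, start=1):
            for _ in range(size):
                out[ids[i]] = f"clade{c}"
                i += 1
        return out

    def clade_members(self, clade_index: int) -> list[str]:
        """Genome ids of the 1-based ``clade_index``."""
        start = sum(self.clade_sizes[: clade_index - 1])
        return self.genome_ids[start : start + self.clade_sizes[clade_index - 1]]

    @property
    def singleton_counts(self) -> list[int]:
        if isinstance(self.singletons_per_genome, int):
            return [self.singletons_per_genome] * self.n_genomes
        return list(self.singletons_per_genome)

    def config_hash(self) -> str:
        payload = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _default_islands(cfg: PopulationConfig) -> tuple[IslandSpec, ...]:
    """One 33 kb island with six nested deletion patterns across the clades."""
    L = cfg.reference_length
    start = int(0.55 * L)
    length = min(33_000, max(2000, L // 10)) if L < 120_000 else 33_000
    B = (int(length * 2 / 33), int(length * 17 / 33))
    C = (int(length * 22 / 33), int(length * 26 / 33))
    D = (int(length * 4 / 33), int(length * 12 / 33))
    E = (0, length)
    F = (int(length * 9 / 33), int(length * 30 / 33))
    deletions: dict[str, tuple[tuple[int, int], ...]] = {}
    if len(cfg.clade_sizes) == 7:
        cd = tuple(sorted((C, D)))
        for g in cfg.clade_members(1) + cfg.clade_members(2):
            deletions[g] = cd
        for g in cfg.clade_members(4):
            deletions[g] = (C,)
        clade5 = cfg.clade_members(5)
        for g in clade5[:-1]:
            deletions[g] = (B,)
        if clade5:
            deletions[clade5[-1]] = (E,)
        clade3 = cfg.clade_members(3)
        if clade3:
            deletions[clade3[-1]] = (F,)
    return (IslandSpec(start=start, length=length, deletions=deletions),)


def _default_insertions(cfg: PopulationConfig) -> tuple[InsertionSpec, ...]:
    L = cfg.reference_length
    if len(cfg.clade_sizes) != 7:
        return ()
    ng = [g for c in range(1, 6) for g in cfg.clade_members(c)]
    clade6 = cfg.clade_members(6)
    plasmid2_carriers = tuple(cfg.clade_members(1)[:2] + cfg.clade_members(2)[:3])
    return (
        InsertionSpec("plasmid1", 30_000, int(0.18 * L), tuple(clade6)),
        InsertionSpec("virus", 17_000, int(0.36 * L), tuple(ng + clade6)),
        InsertionSpec("plasmid2", 35_000, int(0.76 * L), plasmid2_carriers),
    )


def _default_protospacers(cfg: PopulationConfig) -> tuple[ProtospacerPlant, ...]:
    plants = []
    element_ids = [s.element_id for s in (cfg.insertion_specs or ())]
    if "virus" in element_ids:
        plants.append(ProtospacerPlant(0, 2, "virus", 5_000))
    if "plasmid1" in element_ids:
        plants.append(ProtospacerPlant(1, 4, "plasmid1", 8_000))
    if cfg.island_specs:
        # inside deletion C of the default island, echoing self-matches to
        # regions of deletion within the island
        off = int(cfg.island_specs[0].length * 23.5 / 33)
        plants.append(ProtospacerPlant(2 % cfg.crispr_spec.n_arrays, 0, "island0", off))
    return tuple(plants)


def _array_positions(cfg: PopulationConfig) -> list[int]:
    L = cfg.reference_length
    return [int(f * L) for f in (0.08, 0.24, 0.48, 0.88)][: cfg.crispr_spec.n_arrays]


def _array_span(spec: CrisprSpec) -> int:
    return (spec.n_spacers + 1) * spec.repeat_length + spec.n_spacers * spec.spacer_length


def _check_feature_layout(cfg: PopulationConfig) -> None:
    """Planted large features must not overlap on the reference."""
    intervals: list[tuple[int, int, str]] = []
    for i, isl in enumerate(cfg.island_specs or ()):
        intervals.append((isl.start, isl.end, f"island{i}"))
        for g, pairs in isl.deletions.items():
            prev_end = -1
            for s, e in pairs:
                if not (0 <= s < e <= isl.length):
                    raise ValueError(f"deletion {s, e} outside island{i} for {g}")
                if s < prev_end:
                    raise ValueError(f"overlapping deletions within island{i} for {g}")
                prev_end = e
            unknown = set([g]) - set(cfg.genome_ids)
            if unknown:
                raise ValueError(f"unknown genome in island deletions: {unknown}")
    for spec in cfg.insertion_specs or ():
        intervals.append((spec.position, spec.position + 1, spec.element_id))
        unknown = set(spec.carriers) - set(cfg.genome_ids)
        if unknown:
            raise ValueError(f"unknown carrier genome(s): {unknown}")
    span = _array_span(cfg.crispr_spec)
    for i, p in enumerate(_array_positions(cfg)):
        intervals.append((p, p + span, f"array{i}"))
    intervals.sort()
    for (s1, e1, n1), (s2, e2, n2) in zip(intervals, intervals[1:]):
        if s2 < e1 + MIN_EDIT_SPACING:
            raise ValueError(f"planted features overlap or nearly so: {n1} and {n2}")
        if e1 > cfg.reference_length or e2 > cfg.reference_length:
            raise ValueError("planted feature extends past the reference end")


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------


class TruthSnp(NamedTuple):
    position: int
    ref: str
    alt: str
    carriers: tuple[str, ...]
    klass: str  # clade_fixed | private | singleton


class TruthIndel(NamedTuple):
    position: int
    length: int
    type: str  # insertion | deletion | substitution
    carriers: tuple[str, ...]
    ref: str
    alt: str


class TruthIsland(NamedTuple):
    start: int
    end: int
    deletions: dict[str, tuple[tuple[int, int], ...]]  # absolute ref coordinates
    pattern_of: dict[str, str]  # genome -> pattern label (A, B, ...)


class TruthInsertion(NamedTuple):
    element_id: str
    position: int
    length: int
    carriers: tuple[str, ...]
    sequence: str


class TruthArray(NamedTuple):
    start: int
    end: int
    repeat: str
    spacers: tuple[str, ...]


class TruthGene(NamedTuple):
    gene_id: str
    start: int
    end: int
    strand: str


@dataclass
class TruthTable:
    """Ground truth of one simulated population (reference coordinates)."""

    reference: str
    snps: list[TruthSnp]
    indels: list[TruthIndel]
    islands: list[TruthIsland]
    insertions: list[TruthInsertion]
    arrays: list[TruthArray]
    genes: list[TruthGene]
    clades: dict[str, str]
    seed: int

    def validate(self) -> None:
        genomes = set(self.clades)
        for rec in self.snps:
            if not set(rec.carriers) <= genomes:
                raise ValueError(f"invalid carrier ids at SNP {rec.position}")
            clades_hit = {self.clades[g] for g in rec.carriers}
            if rec.klass == "singleton" and len(rec.carriers) != 1:
                raise ValueError("singleton with carrier count != 1")
            if rec.klass == "private" and (len(rec.carriers) < 2 or len(clades_hit) != 1):
                raise ValueError("private allele must have >=2 carriers in one clade")
            if rec.klass == "clade_fixed":
                clade = clades_hit.pop() if len(clades_hit) == 1 else None
                if clade is None or set(rec.carriers) != {
                    g for g, c in self.clades.items() if c == clade
                }:
                    raise ValueError("clade_fixed allele must cover exactly one clade")

    def snp_class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.snps:
            out[rec.klass] = out.get(rec.klass, 0) + 1
        return out

    def island_presence(self, island_index: int = 0) -> dict[str, bool]:
        isl = self.islands[island_index]
        return {g: g not in isl.deletions for g in self.clades}

    def element_presence(self, element_id: str) -> dict[str, bool]:
        spec = next(i for i in self.insertions if i.element_id == element_id)
        return {g: g in spec.carriers for g in self.clades}


def pattern_labels(
    breakpoints_of: dict[str, tuple[tuple[int, int], ...]],
) -> dict[str, str]:
    """Assign A, B, C... labels to identical breakpoint-pair groups.

    Groups are ordered by descending size, then by leftmost coordinate (a
    group with no deletions sorts first among equal sizes).
    """
    groups: dict[tuple, list[str]] = {}
    for g, pairs in breakpoints_of.items():
        groups.setdefault(tuple(pairs), []).append(g)
    ordered = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1]), kv[0][0][0] if kv[0] else -1),
    )
    labels = {}
    for label_i, (_pairs, members) in enumerate(ordered):
        label = chr(ord("A") + label_i)
        for g in members:
            labels[g] = label
    return labels


# ---------------------------------------------------------------------------
# reference and population synthesis
# ---------------------------------------------------------------------------


def generate_reference(length: int, gc_fraction: float, seed: int) -> Genome:
    """Random reference sequence with the requested GC content.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2, so the realised GC
    fraction is binomial around the target (within ~1% for >=100 kb).
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, length, gc_fraction)
    return Genome("REF", seq)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.int64)
    return decode(codes)


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[11]
        _SENSE_CODONS = sorted(table.forward_table)
    return _SENSE_CODONS


def simulate_population(config: PopulationConfig) -> tuple[list[Genome], TruthTable]:
    """Generate the population and its ground truth.

    Each genome is the reference with exactly its planted edits applied;
    identical (config, seed) inputs yield byte-identical outputs.
    """
    cfg = config
    # a child stream distinct from the reference generator's (same entropy,
    # different spawn key), so planted features never echo reference bases
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    L = cfg.reference_length
    ref = list(generate_reference(L, cfg.gc_fraction, cfg.seed).seq)

    # CRISPR arrays: identical repeats and spacers written into the reference
    spec = cfg.crispr_spec
    repeat = _random_sequence(rng, spec.repeat_length, cfg.gc_fraction)
    arrays: list[TruthArray] = []
    for pos in _array_positions(cfg):
        spacers = tuple(
            _random_sequence(rng, spec.spacer_length, cfg.gc_fraction)
            for _ in range(spec.n_spacers)
        )
        seq = repeat + "".join(s + repeat for s in spacers)
        ref[pos : pos + len(seq)] = seq
        arrays.append(TruthArray(pos, pos + len(seq), repeat, spacers))

    # protein-coding genes: sense codons only, so reading frames are clean
    genes: list[TruthGene] = []
    if cfg.plant_genes:
        genes = _plant_genes(cfg, rng, ref)

    # mobile elements (not part of the reference), compositionally distinct
    elements: dict[str, str] = {}
    for ins in cfg.insertion_specs:
        gc = min(0.95, cfg.gc_fraction + 0.05)
        elements[ins.element_id] = _random_sequence(rng, ins.length, gc)

    # planted protospacers: copy spacers into elements / islands
    for plant in cfg.protospacer_plants or ():
        spacer = arrays[plant.array].spacers[plant.spacer]
        if plant.target.startswith("island"):
            isl = cfg.island_specs[int(plant.target[len("island") :])]
            p = isl.start + plant.offset
            ref[p : p + len(spacer)] = spacer
        else:
            elem = elements[plant.target]
            off = plant.offset
            elements[plant.target] = elem[:off] + spacer + elem[off + len(spacer) :]

    ref_seq = "".join(ref)

    # ---- small variants ----------------------------------------------------
    allowed = _variant_mask(cfg, arrays)
    allowed_pos = np.flatnonzero(allowed)
    taken: list[int] = []

    def draw_position(span: int = 1) -> int:
        for _ in range(10_000):
            p = int(allowed_pos[rng.integers(allowed_pos.size)])
            if p + span > L or not allowed[p : p + span].all():
                continue
            i = bisect_left(taken, p)
            ok = True
            if i > 0 and p - taken[i - 1] < MIN_EDIT_SPACING + span:
                ok = False
            if i < len(taken) and taken[i] - p < MIN_EDIT_SPACING + span:
                ok = False
            if ok:
                insort(taken, p)
                return p
        raise RuntimeError("could not place a variant with the required spacing")

    bases = "ACGT"

    def alt_base(p: int) -> str:
        choices = [b for b in bases if b != ref_seq[p]]
        return choices[rng.integers(3)]

    snps: list[TruthSnp] = []
    for c in range(1, len(cfg.clade_sizes) + 1):
        clade_members = tuple(cfg.clade_members(c))
        for _ in range(cfg.fixed_snps_per_clade[c - 1]):
            p = draw_position()
            snps.append(TruthSnp(p, ref_seq[p], alt_base(p), clade_members, "clade_fixed"))
    for c in range(1, len(cfg.clade_sizes) + 1):
        members = cfg.clade_members(c)
        for _ in range(cfg.private_snps_per_clade[c - 1]):
            p = draw_position()
            size = int(rng.integers(2, len(members)))  # 2 <= size < clade size
            carriers = tuple(sorted(rng.choice(members, size=size, replace=False)))
            snps.append(TruthSnp(p, ref_seq[p], alt_base(p), carriers, "private"))
    for g, n_single in zip(cfg.genome_ids, cfg.singleton_counts):
        for _ in range(n_single):
            p = draw_position()
            snps.append(TruthSnp(p, ref_seq[p], alt_base(p), (g,), "singleton"))
    snps.sort(key=lambda r: r.position)

    indels: list[TruthIndel] = []
    kinds = ["insertion", "insertion", "deletion"]
    for i in range(cfg.small_indels):
        kind = kinds[i % 3]
        length = int(rng.integers(1, 11))
        carrier = cfg.genome_ids[int(rng.integers(cfg.n_genomes))]
        if kind == "deletion":
            p = _draw_stable_deletion(rng, ref_seq, draw_position, length)
            indels.append(
                TruthIndel(p, length, "deletion", (carrier,), ref_seq[p : p + length], "")
            )
        else:
            p = draw_position()
            ins = _stable_insertion(rng, ref_seq, p, length, cfg.gc_fraction)
            indels.append(TruthIndel(p, length, "insertion", (carrier,), "", ins))
    for _ in range(cfg.small_substitutions):
        length = int(rng.integers(2, 11))
        p = draw_position(span=length)
        carrier = cfg.genome_ids[int(rng.integers(cfg.n_genomes))]
        alt = "".join(alt_base(p + j) for j in range(length))
        indels.append(
            TruthIndel(p, length, "substitution", (carrier,), ref_seq[p : p + length], alt)
        )
    indels.sort(key=lambda r: r.position)

    # ---- islands and insertions -------------------------------------------
    islands: list[TruthIsland] = []
    for isl in cfg.island_specs:
        abs_del = {
            g: tuple((isl.start + s, isl.start + e) for s, e in pairs)
            for g, pairs in isl.deletions.items()
        }
        rel_all = {g: isl.deletions.get(g, ()) for g in cfg.genome_ids}
        islands.append(
            TruthIsland(isl.start, isl.end, abs_del, pattern_labels(rel_all))
        )
    insertions = [
        TruthInsertion(s.element_id, s.position, s.length, s.carriers, elements[s.element_id])
        for s in cfg.insertion_specs
    ]

    truth = TruthTable(
        reference=ref_seq,
        snps=snps,
        indels=indels,
        islands=islands,
        insertions=insertions,
        arrays=arrays,
        genes=genes,
        clades=cfg.clade_of,
        seed=cfg.seed,
    )
    truth.validate()

    genomes = [Genome(g, apply_truth(truth, g)) for g in cfg.genome_ids]
    logger.info(
        "simulated %d genomes (seed=%d, config=%s)",
        len(genomes),
        cfg.seed,
        cfg.config_hash(),
    )
    return genomes, truth


def _variant_mask(cfg: PopulationConfig, arrays: Sequence[TruthArray]) -> np.ndarray:
    L = cfg.reference_length
    pad = MIN_EDIT_SPACING
    mask = np.ones(L, dtype=bool)
    mask[:1000] = False
    mask[-1000:] = False
    for arr in arrays:
        mask[max(0, arr.start - pad) : arr.end + pad] = False
    for isl in cfg.island_specs:
        mask[max(0, isl.start - pad) : isl.end + pad] = False
    for ins in cfg.insertion_specs:
        mask[max(0, ins.position - pad) : ins.position + pad] = False
    return mask


def _draw_stable_deletion(rng, ref_seq: str, draw_position, length: int) -> int:
    """Position whose deletion is left-normalisation stable (not shiftable)."""
    for _ in range(1000):
        p = draw_position(span=length)
        if p > 0 and ref_seq[p - 1] != ref_seq[p + length - 1]:
            return p
    raise RuntimeError("could not place a left-stable deletion")


def _stable_insertion(rng, ref_seq: str, p: int, length: int, gc: float) -> str:
    """Inserted sequence that cannot be left-shifted at position p."""
    for _ in range(1000):
        ins = _random_sequence(rng, length, gc)
        if p == 0 or ins[-1] != ref_seq[p - 1]:
            return ins
    raise RuntimeError("could not draw a left-stable insertion")


def _plant_genes(cfg: PopulationConfig, rng, ref: list[str]) -> list[TruthGene]:
    """Tile non-reserved reference space with stop-free coding genes."""
    L = cfg.reference_length
    reserved: list[tuple[int, int]] = [(0, 1000), (L - 1000, L)]
    span = _array_span(cfg.crispr_spec)
    for p in _array_positions(cfg):
        reserved.append((p - 100, p + span + 100))
    for isl in cfg.island_specs:
        reserved.append((isl.start - 200, isl.end + 200))
    for ins in cfg.insertion_specs:
        reserved.append((ins.position - 200, ins.position + 200))
    reserved.sort()
    merged: list[list[int]] = []
    for s, e in reserved:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    free: list[tuple[int, int]] = []
    prev = 0
    for s, e in merged:
        if s > prev:
            free.append((prev, s))
        prev = max(prev, e)
    if prev < L:
        free.append((prev, L))

    codons = _sense_codons()
    genes: list[TruthGene] = []
    glen, gap = cfg.gene_length, cfg.gene_spacing
    gi = 0
    for s, e in free:
        p = s + gap
        while p + glen + gap <= e:
            strand = "+" if gi % 2 == 0 else "-"
            n_codons = glen // 3
            coding = "".join(codons[int(i)] for i in rng.integers(len(codons), size=n_codons))
            placed = coding if strand == "+" else revcomp(coding)
            ref[p : p + glen] = placed
            gi += 1
            genes.append(TruthGene(f"gene{gi:04d}", p, p + glen, strand))
            p += glen + gap
    return genes


def apply_truth(truth: TruthTable, genome_id: str) -> str:
    """Reconstruct one genome by applying its planted edits to the reference.

    Raises if edits overlap. Used both to emit genomes and, independently,
    to verify the round-trip property in tests.
    """
    edits: list[tuple[int, int, str]] = []  # (pos, ref_len, replacement)
    for rec in truth.snps:
        if genome_id in rec.carriers:
            edits.append((rec.position, 1, rec.alt))
    for rec in truth.indels:
        if genome_id in rec.carriers:
            if rec.type == "insertion":
                edits.append((rec.position, 0, rec.alt))
            elif rec.type == "deletion":
                edits.append((rec.position, rec.length, ""))
            else:
                edits.append((rec.position, rec.length, rec.alt))
    for isl in truth.islands:
        for s, e in isl.deletions.get(genome_id, ()):
            edits.append((s, e - s, ""))
    for ins in truth.insertions:
        if genome_id in ins.carriers:
            edits.append((ins.position, 0, ins.sequence))
    edits.sort()
    for (p1, l1, _), (p2, _, _) in zip(edits, edits[1:]):
        if p2 < p1 + l1:
            raise ValueError(f"overlapping planted edits in {genome_id}")
    seq = truth.reference
    out = []
    prev = 0
    for p, ref_len, repl in edits:
        out.append(seq[prev:p])
        out.append(repl)
        prev = p + ref_len
    out.append(seq[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Uniform-coverage single-end reads from one genome.

    Reads are held as an encoded (n_reads, read_length) uint8 matrix; the
    string view and FASTQ serialisation are generated on demand.
    """

    genome_id: str
    matrix: np.ndarray
    read_length: int
    coverage: float
    error_rate: float

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    def sequences(self):
        for row in self.matrix:
            yield decode(row)

    def reads(self):
        qual = "I" * self.read_length
        for seq in self.sequences():
            yield seq, qual

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i, (seq, qual) in enumerate(self.reads()):
                fh.write(f"@{self.genome_id}_read{i}\n{seq}\n+\n{qual}\n")


def simulate_reads(
    genome: Genome,
    coverage: float,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Draw reads with uniform start positions and i.i.d. substitution errors."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_length > len(genome.seq):
        raise ValueError("read_length exceeds genome length")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(coverage * len(genome.seq) / read_length))
    enc = encode(genome.seq)
    starts = rng.integers(0, len(genome.seq) - read_length + 1, size=n)
    matrix = enc[starts[:, None] + np.arange(read_length)[None, :]]
    if error_rate > 0:
        errs = rng.random(matrix.shape) < error_rate
        shift = rng.integers(1, 4, size=int(errs.sum()))
        matrix = matrix.copy()
        matrix[errs] = (matrix[errs] + shift) % 4
    return ReadSet(genome.id, matrix, read_length, coverage, error_rate)


# ---------------------------------------------------------------------------
# run directory output
# ---------------------------------------------------------------------------


def write_run(outdir, genomes: list[Genome], truth: TruthTable, config: PopulationConfig) -> None:
    """Write FASTA per genome, reference, GFF3 genes, truth TSVs and config YAML."""
    from pathlib import Path

    from . import io as cpio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cpio.write_fasta(out / "reference.fasta", [("REF", truth.reference)])
    for g in genomes:
        cpio.write_fasta(out / f"{g.id}.fasta", [(g.id, g.seq)])
    cpio.write_gff3(
        out / "genes.gff3",
        "REF",
        [(g.gene_id, g.start, g.end, g.strand, "gene") for g in truth.genes],
    )
    with open(out / "truth_snps.tsv", "w") as fh:
        fh.write("position\tref\talt\tclass\tcarriers\n")
        for r in truth.snps:
            fh.write(f"{r.position}\t{r.ref}\t{r.alt}\t{r.klass}\t{','.join(r.carriers)}\n")
    with open(out / "truth_indels.tsv", "w") as fh:
        fh.write("position\tlength\ttype\tcarriers\n")
        for r in truth.indels:
            fh.write(f"{r.position}\t{r.length}\t{r.type}\t{','.join(r.carriers)}\n")
    with open(out / "truth_islands.tsv", "w") as fh:
        fh.write("start\tend\tgenome\tpattern\tdeletions\n")
        for isl in truth.islands:
            for g, label in sorted(isl.pattern_of.items()):
                dels = ";".join(f"{s}-{e}" for s, e in isl.deletions.get(g, ()))
                fh.write(f"{isl.start}\t{isl.end}\t{g}\t{label}\t{dels}\n")
    with open(out / "clades.tsv", "w") as fh:
        fh.write("genome\tclade\n")
        for g, c in truth.clades.items():
            fh.write(f"{g}\t{c}\n")
    cfg_dict = dataclasses.asdict(config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": _yamlable(cfg_dict), "config_hash": config.config_hash()}, fh)
    logger.info("run written to %s (seed=%d, config=%s)", out, config.seed, config.config_hash())


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    return obj
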