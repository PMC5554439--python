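"""End-to-end orchestration: genomes in, population analysis out.

Thin glue over the analysis modules, used by the example scripts, the
acceptance checks and downstream notebooks; every step is available
individually from its own module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import coverage as covmod
from . import crispr as crisprmod
from . import islands as islandmod
from . import popstats, structure
from .core import (
    AnchorChain,
    CoreBlock,
    SmallVariant,
    SnpMatrix,
    build_snp_matrix,
    call_small_variants,
    extract_core_blocks,
    find_anchors,
)
from .simulate import Genome, simulate_reads


@dataclass
class CoreResult:
    chains: dict[str, AnchorChain]
    variants: dict[str, list[SmallVariant]]
    blocks: list[CoreBlock]
    matrix: SnpMatrix

    @property
    def core_length(self) -> int:
        return sum(b.length for b in self.blocks)

    def unique_non_snp_variants(self) -> list[SmallVariant]:
        seen = {}
        for vs in self.variants.values():
            for v in vs:
                if v.type != "snp":
                    seen.setdefault(v.key(), v)
        return [seen[k] for k in sorted(seen)]


def analyze_core(
    reference: str,
    genomes: Sequence[Genome],
    min_match: int = 20,
) -> CoreResult:
    """Anchor every genome, call small variants, build blocks and SNP matrix."""
    chains: dict[str, AnchorChain] = {}
    variants: dict[str, list[SmallVariant]] = {}
    for g in genomes:
        chain = find_anchors(reference, g.seq, min_match=min_match, genome=g.id)
        chains[g.id] = chain
        variants[g.id] = call_small_variants(reference, g.seq, chain)
    blocks = extract_core_blocks(list(chains.values()), len(reference))
    matrix = build_snp_matrix(variants, blocks, reference)
    return CoreResult(chains, variants, blocks, matrix)


def analyze_variable_genome(
    core: CoreResult,
    reference: str,
    genomes: Sequence[Genome],
    elements: Sequence[tuple[str, str]] = (),
    gap_tolerance: int = 100,
) -> list[islandmod.VariableRegion]:
    """Reference islands plus element-backed regions, presence-verified."""
    profiles = islandmod.build_absence_profiles(list(core.chains.values()), len(reference))
    regions = islandmod.call_islands(profiles, gap_tolerance=gap_tolerance)
    genome_seqs = [(g.id, g.seq) for g in genomes]
    regions += islandmod.element_regions(list(elements), genome_seqs)
    return regions


def deletion_patterns(
    reference: str,
    island_interval: tuple[int, int],
    genomes: Sequence[Genome],
    coverage: float = 30.0,
    read_length: int = 100,
    seed: int = 0,
    threshold: float = covmod.DEFAULT_THRESHOLD,
    tolerance: int = 250,
) -> dict[str, covmod.DeletionCall]:
    """The read-coverage deletion-pattern procedure over one reference island."""
    s, e = island_interval
    island_seq = reference[s:e]
    calls = []
    for i, g in enumerate(genomes):
        reads = simulate_reads(g, coverage, read_length, 0.0, seed=seed * 100_003 + i)
        cov = covmod.compute_coverage(reads, island_seq, island_id=f"{s}-{e}")
        calls.append(
            covmod.call_breakpoints(cov, threshold=threshold, smooth_window=2 * read_length)
        )
    return covmod.group_patterns(calls, tolerance=tolerance)


def crispr_survey(genomes: Sequence[Genome]) -> dict[str, list[crisprmod.CrisprArray]]:
    return {g.id: crisprmod.detect_arrays(g.seq, genome=g.id) for g in genomes}


def infer_clades(matrix: SnpMatrix, min_support: int = 1):
    tree = structure.nj_tree(matrix)
    return tree, structure.assign_clades(matrix, tree, min_support=min_support)


@dataclass
class StudyResult:
    """Everything the default-population analysis produces, plus ground truth."""

    config: object
    genomes: list[Genome]
    truth: object
    core: CoreResult
    classification: object
    divergence: object
    tajima_overall: float | None
    tree: object
    clades: object
    regions: list
    patterns: dict[str, covmod.DeletionCall]
    arrays: dict[str, list[crisprmod.CrisprArray]]


def run_default_study(seed: int = 0, config=None) -> StudyResult:
    """Simulate the default clonal population and run every analysis stage.

    The one entry point behind the worked example and the acceptance
    checks: 47 genomes / 7 clades on a 500 kb reference with the default
    planted variant, island, element and CRISPR structure.
    """
    from .popstats import classify_alleles, divergence, tajimas_d_from_matrix
    from .simulate import PopulationConfig, simulate_population

    cfg = config if config is not None else PopulationConfig(seed=seed)
    genomes, truth = simulate_population(cfg)
    core = analyze_core(truth.reference, genomes)
    classification = classify_alleles(core.matrix, truth.clades)
    div = divergence(core.matrix, core.core_length)
    tajima = tajimas_d_from_matrix(core.matrix)
    tree, clades = infer_clades(core.matrix)
    elements = [(i.element_id, i.sequence) for i in truth.insertions]
    regions = analyze_variable_genome(core, truth.reference, genomes, elements)
    isl = truth.islands[0]
    patterns = deletion_patterns(
        truth.reference, (isl.start, isl.end), genomes, seed=seed
    )
    arrays = crispr_survey(genomes)
    return StudyResult(
        cfg, genomes, truth, core, classification, div, tajima, tree, clades,
        regions, patterns, arrays,
    )
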