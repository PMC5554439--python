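import numpy as np
import pytest

from clonalpop.simulate import (
    CrisprSpec,
    Genome,
    InsertionSpec,
    IslandSpec,
    PopulationConfig,
    generate_reference,
    simulate_population,
)


def small_config(seed: int = 11, **overrides) -> PopulationConfig:
    """A 60 kb, 8-genome, 2-clade population: fast enough for unit tests."""
    island = IslandSpec(
        start=36_000,
        length=6_000,
        deletions={
            "NG05_01": ((1000, 3000),),
            "NG05_02": ((1000, 3000),),
            "GG12_01": ((0, 6000),),
            "GG12_02": ((0, 6000),),
        },
    )
    defaults = dict(
        reference_length=60_000,
        n_genomes=8,
        clade_sizes=(4, 4),
        fixed_snps_per_clade=(2, 3),
        private_snps_per_clade=(2, 2),
        singletons_per_genome=1,
        small_indels=6,
        small_substitutions=2,
        island_specs=(island,),
        insertion_specs=(
            InsertionSpec("plasmidA", 4_000, 12_000, ("NG05_01", "NG05_02")),
        ),
        crispr_spec=CrisprSpec(n_arrays=2, n_spacers=4, repeat_length=24, spacer_length=36),
        protospacer_plants=(),
        gene_length=300,
        gene_spacing=100,
        seed=seed,
    )
    defaults.update(overrides)
    cfg = PopulationConfig(**defaults)
    # genome ids for a (4, 4) clade layout are NG05_01..04 + GG12-style rest;
    # sanity-check the island deletion carriers exist
    assert set(island.deletions) <= set(cfg.genome_ids)
    return cfg


@pytest.fixture(scope="session")
def small_population():
    cfg = small_config()
    genomes, truth = simulate_population(cfg)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def small_core(small_population):
    from clonalpop.pipeline import analyze_core

    cfg, genomes, truth = small_population
    return analyze_core(truth.reference, genomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_100k():
    return generate_reference(100_000, 0.37, seed=5)


def make_genome(name: str, seq: str) -> Genome:
    return Genome(name, seq)
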