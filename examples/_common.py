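"""Shared small population used by the example scripts (fast to simulate)."""

from clonalpop.simulate import (
    CrisprSpec,
    InsertionSpec,
    IslandSpec,
    PopulationConfig,
    simulate_population,
)


def small_population(seed: int = 11):
    """An 80 kb, 10-genome, 2-clade population with one island, one
    integrated element, and two CRISPR arrays."""
    island = IslandSpec(
        start=48_000,
        length=8_000,
        deletions={
            "NG05_01": ((1500, 4000),),
            "NG05_02": ((1500, 4000),),
            "GG12_01": ((0, 8000),),
            "GG12_02": ((0, 8000),),
        },
    )
    cfg = PopulationConfig(
        reference_length=80_000,
        n_genomes=10,
        clade_sizes=(5, 5),
        fixed_snps_per_clade=(3, 4),
        private_snps_per_clade=(2, 2),
        singletons_per_genome=1,
        small_indels=6,
        small_substitutions=2,
        island_specs=(island,),
        insertion_specs=(
            InsertionSpec("plasmidA", 5_000, 16_000, ("NG05_01", "NG05_02", "NG05_03")),
        ),
        crispr_spec=CrisprSpec(n_arrays=2, n_spacers=5, repeat_length=24, spacer_length=38),
        protospacer_plants=(),
        gene_length=300,
        gene_spacing=100,
        seed=seed,
    )
    genomes, truth = simulate_population(cfg)
    return cfg, genomes, truth
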