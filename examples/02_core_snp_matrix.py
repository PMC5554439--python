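"""Core-genome comparison: anchors, small variants, core blocks, SNP matrix.

Anchors every genome against the reference, resolves small inter-anchor
gaps into variant calls, intersects coverage into core blocks (> 500 bp,
shared by all genomes) and assembles the core SNP matrix.
"""

from _common import small_population

from clonalpop.pipeline import analyze_core

cfg, genomes, truth = small_population()
core = analyze_core(truth.reference, genomes)

print(f"core blocks: {len(core.blocks)}  total core length: {core.core_length:,} bp")
print(f"(reference is {len(truth.reference):,} bp; the island accounts for the gap)")
print(f"SNP matrix: {len(core.matrix.genomes)} genomes x {core.matrix.n_sites} sites")
print(f"planted SNPs: {len(truth.snps)}")

recovered = {int(p) for p in core.matrix.positions}
planted = {r.position for r in truth.snps}
print(f"recovered SNP positions == planted: {recovered == planted}")

non_snp = core.unique_non_snp_variants()
print(f"indels/substitutions called: {len(non_snp)} (planted {len(truth.indels)})")
# A matrix column == a polymorphic core site; the matrix is the substrate
# for classification, divergence, Tajima's D and the clonal phylogeny.
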