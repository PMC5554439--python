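"""CRISPR arrays, spacer conservation, and spacer matching.

Detects arrays with a CRT-like tandem-repeat scan, confirms spacer content
is identical across genomes, and runs the word-size-7 ungapped spacer
search with Karlin-Altschul e-values (cutoff 0.001).
"""

from _common import small_population

from clonalpop.crispr import (
    conservation_matrix,
    detect_arrays,
    find_self_targets,
    karlin_altschul_params,
    match_spacers,
)

cfg, genomes, truth = small_population()

arrays = {g.id: detect_arrays(g.seq, genome=g.id) for g in genomes[:4]}
first = arrays[genomes[0].id]
print(f"arrays per genome: {[len(a) for a in arrays.values()]}")
for a in first:
    print(f"  {a.genome}: {a.start}-{a.end}, repeat {len(a.repeat)} bp, "
          f"{len(a.spacers)} spacers")

conserved = conservation_matrix(arrays)
print(f"spacer content identical across genomes: {len(set(conserved.values())) == 1}")

lam, K, H = karlin_altschul_params()
print(f"score system +2/-3: lambda={lam:.3f}, K={K:.3f} (solved, not tabulated)")

# all-vs-all spacer comparison within one genome: distinct spacers don't match
spacers = [(f"a{i}s{j}", s) for i, a in enumerate(first) for j, s in enumerate(a.spacers)]
hits = match_spacers(spacers, spacers)
cross = [h for h in hits if h.query != h.subject]
print(f"cross-matches among {len(spacers)} distinct spacers at E<=0.001: {len(cross)}")

targets = find_self_targets({genomes[0].id: first}, [(genomes[0].id, genomes[0].seq)])
print(f"self-targets outside arrays in {genomes[0].id}: {len(targets)} "
      f"(none planted in this configuration)")
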