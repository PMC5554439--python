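"""Coverage-threshold deletion breakpoints within the island.

Simulates 30x reads per genome, maps them onto the extracted island
sequence, calls maximal runs of depth < 10x as (drop, recover) breakpoint
pairs, and groups genomes sharing breakpoints into deletion patterns.
"""

from _common import small_population

from clonalpop.pipeline import deletion_patterns

cfg, genomes, truth = small_population()
isl = truth.islands[0]
grouped = deletion_patterns(
    truth.reference, (isl.start, isl.end), genomes, coverage=30, read_length=100, seed=2
)

by_pattern = {}
for g, call in grouped.items():
    by_pattern.setdefault(call.pattern, []).append((g, call.pairs))

for label in sorted(by_pattern):
    members = by_pattern[label]
    pairs = members[0][1]
    desc = ", ".join(f"{s}-{e}" for s, e in pairs) if pairs else "intact"
    print(f"pattern {label}: {desc}  ({len(members)} genomes: "
          f"{', '.join(g for g, _ in members)})")

agree = sum(1 for g, label in isl.pattern_of.items() if grouped[g].pattern == label)
print(f"pattern assignment matches planted truth for {agree}/{len(genomes)} genomes")
# breakpoints land within one read length of the planted coordinates
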