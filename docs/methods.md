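# Methods

This note documents the models, procedures and numerical choices behind
`clonalpop`, what the synthetic populations do and do not emulate, and the
design decisions taken where the design was genuinely open.

## Setting and assumptions

The pipeline targets *near-clonal* populations: a sample of assembled
genomes, each > 95% (in practice > 99.9%) identical to a designated
ancestral reference, where variation consists of sparse small variants,
large presence/absence intervals (genomic islands), integrated mobile
elements, and conserved CRISPR loci. Under these conditions a full
whole-genome aligner is unnecessary: exact sequence matches that are
unique in both genomes are dense everywhere except at variant sites, and
collinearity holds because rearrangements and inversions are out of scope
(they are rare at this divergence and the simulator never produces them —
analyses of rearranged genomes need a true aligner).

## Core-genome comparison

**Anchoring.** Each genome is compared to the reference via shared k-mers
(default k = 20, collision-free integer packing) that occur exactly once
in both sequences. Same-diagonal runs merge into exact-match segments,
which are chained into the highest-total-length collinear subset by a
weighted longest-increasing-subsequence DP (ties broken toward smaller
reference start, for determinism). Two numerical details matter:

- *Junction overrun.* At a deletion or insertion junction the flanking
  anchor can coincidentally extend a few bases past the true breakpoint
  (each extra base survives with probability 1/4), overlapping its
  neighbour. Chaining therefore tolerates overlaps up to 50 bp and trims
  the later anchor afterwards; without this, whole segments between two
  junctions can be dropped.
- *Uniqueness dropout.* Inside repeated loci (CRISPR repeats) k-mers are
  non-unique and anchors break even though the sequences are identical;
  adjacent chained anchors separated by identical sequence on both sides
  are therefore re-joined.

k = 20 is unique at the 2 Mb scale (expected number of duplicated 20-mers
in a random 2 Mb sequence is ≈ 4, and duplicates only shorten anchors);
with variant spacing of ≥ 50 bp every inter-variant interval contains
anchoring k-mers.

**Small variants.** Inter-anchor gaps ≤ 50 bp on both sides are resolved
into records: equal-length gaps are positionally aligned (mismatch runs →
SNP when length 1, multi-base substitution otherwise); pure one-sided gaps
are indels; mixed unequal gaps go through an affine-gap pairwise alignment
(match +1, mismatch −1, gap open −3, extend −1 — gap-averse so isolated
substitutions are not decomposed into gap artifacts). Indels are
left-normalised (shifted to their leftmost equivalent placement, the usual
VCF convention) so call sets are canonical and comparable. Gaps of
51–999 bp are reported as *intermediate deletions* in a side table and
excluded from both SNP statistics and island calls — the island definition
starts at 1000 bp and small variants end at 50 bp, and the middle is
deliberately left out of both rather than silently absorbed. Gaps
≥ 1000 bp feed the island stage.

A note on representational ambiguity: a multi-base substitution whose
content accidentally echoes shifted context can tie with (or lose to) a
gapped decomposition under *any* scoring; the caller's representation is
the positional one, and the oracle tests that demand exact equality with a
full DP alignment therefore plant SNPs and indels only.

**Core blocks.** Per genome, anchors joined across small-variant gaps form
covered reference intervals; the intersection over genomes, split at any
genome's large gap (including zero-reference-width insertion points), and
filtered to length > 500 bp, yields the core blocks. The SNP matrix has
one column per reference position carrying a SNP record inside a core
block; genomes without a record carry the reference allele; conflicting
alleles for one genome at one position are an error, not a vote.

## Population statistics

**Classification.** Per site, the carrier set is the genomes whose allele
differs from the reference. Classes partition biallelic sites: *singleton*
(one carrier), *private* (≥ 2 carriers, all in one clade), *shared*
(carriers spanning clades). *Fixed-vs-reference* (all genomes carry the
alternative) is an orthogonal flag, as is *fixed-in-clade* (carriers are
exactly one whole clade) — the latter is what "unique fixed SNPs per
clade" counts. Sites with two or more alternative alleles stay in S and π
but are excluded from the biallelic private tally.

**Divergence.** Both statistics are reported rather than guessing which
one a given table means: `d_total` = polymorphism count / core length, and
`d_pi` = mean pairwise difference count / core length. For a 47-genome
sample of mostly-singleton variation they differ by an order of magnitude.

**Tajima's D** is computed from the textbook constants
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) with π taken over the concatenated core
SNP columns (monomorphic core positions contribute zero to both π and S,
and cancel from the statistic's inputs as used here). D is evaluated
overall and per clade; it is *undefined* for S = 0 or n < 4 and signalled
as such (an exception / `None`), never silently 0. No significance testing
against coalescent simulations is attempted.

**Nei–Gojobori / dn/ds.** Potential synonymous sites per codon are the
expected fraction of the three single-base changes per position that
preserve the amino acid (genetic code 11), summed over genes; changes to a
stop codon count as nonsynonymous (flagged *nonsense*), so
N_sites + S_sites = 3 × codon count exactly. Each coding SNP is classified
by substituting its alternative base into the reference codon (minus-strand
genes via the reverse complement). dn/ds = (N_obs/N_sites)/(S_obs/S_sites)
with no multiple-hit correction: at divergences of ~10⁻⁴ and below the
Jukes–Cantor correction is orders of magnitude below the reported
precision. Genes must be frame-consistent (length divisible by 3, no
internal stop in the reference frame) — violations raise.

## Variable genome

Per genome, reference intervals with no aligned coverage and length
≥ 1000 bp form its absence profile. Candidate islands are *maximal* union
intervals absent from ≥ 1 genome; a genome counts as absent if any of its
absence intervals overlaps the island (per-genome realised sub-intervals
are kept, since different genomes may miss different parts). Islands
absent from exactly one genome are removed — in real data such calls are
dominated by misassemblies. Surviving islands within 100 bp of each other
merge into variable regions (whole-genome aligners tend to fragment one
region into several islands; the tolerance is a config key).

Integrated elements (plasmid- or virus-like) are absent from the
reference, so they cannot be reference intervals; they are carried as
element-backed variable regions whose per-genome presence comes from
`verify_presence`: the fraction of the element covered by exact 20-mers
shared with the genome, present iff ≥ 50%. On error-free assemblies exact
anchors subsume an identity threshold (anchored bases are 100% identical);
both the coverage and the nominal identity knob are parameters. The 50%
rule deliberately counts genomes retaining half an island as "present",
so nested partial deletions register as present for their retained
segments.

## Deletion patterns from read coverage

Reads of each genome (simulated here: uniform starts, i.i.d. substitution
errors) are placed on the extracted island sequence by a purpose-built
seeded placer — exact 20-mer seeds at three offsets, best locus with ≤ 3
mismatches, full read within the island; it is not a general aligner and
is not indel- or quality-aware. Depth is median-filtered with a window of
2 × read length (raw per-base dips at SNP clusters would otherwise
fragment calls), then maximal runs with depth strictly below the threshold
(default 10×; exactly 10× is *not* a deletion) and span ≥ 200 bp become
(drop, recover) pairs; a genome lacking the island entirely yields one
full-length pair. Edge ramps (reads must lie fully inside the island)
stay below the 200 bp minimum span at 30× / 100 bp reads, so island ends
are not spuriously called. Genomes whose pair lists agree within a
tolerance (default 250 bp ≈ 2.5 read lengths; breakpoint localisation
error is bounded by one read length at ≥ 20× error-free coverage) share a
pattern label; labels run A, B, C… by descending group size then leftmost
coordinate, so the intact group of a mostly-intact population is "A".
Raising the threshold can only widen sub-threshold runs, so called spans
are monotone in the threshold.

## CRISPR

**Detection** is a k-mer-seeded tandem-repeat scan with CRT-like
constraints: seeds are 16-mers recurring ≥ 3 times with successive
spacings inside the repeat+spacer period window [38, 86]; each run is
extended to the maximal common repeat across all copies (an over-long
common repeat is rejected, not truncated — a 50 bp tandem repeat must not
masquerade as a 38 bp repeat with longer spacers) and validated against
repeat length 19–38 bp and spacer lengths 19–48 bp. Runs rich in copies
claim their locus first, because k-mers spanning a spacer/repeat junction
can form shorter competing runs when spacer ends coincide. The detector
assumes error-free assemblies and identical repeat copies; degenerate
repeats would need CRT's mismatch tolerance, which is out of scope. On
random 100 kb sequences the false-positive rate is ~0 (a 16-mer recurring
three times at bounded spacing is vanishingly unlikely).

**Matching** is word-seeded (word size 7) ungapped local alignment scored
+2/−3, both strands, with e-values E = K·m·n·e^(−λS). λ solves
E[e^(λS)] = 1 for the aligned-pair score distribution under uniform base
composition (λ ≈ 0.634), and K follows the lattice-case formula
K = dλe^(−2σ)/(H(1−e^(−λd))) with σ evaluated by convolving the score
distribution (K ≈ 0.408); for the ±1 system the implementation reproduces
the closed forms λ = ln 3, K = 1/3 exactly, and Monte Carlo tallies of
maximal segment scores confirm the tail calibration. The reported matches
keep the best non-overlapping hits per (query, subject); the e-value
behaviour is calibrated, not bit-identical to any particular BLAST build,
and the reward/penalty pair is a config key. Self-targets are spacer hits
on the spacer's own genome that fall outside every detected array,
annotated by overlap with supplied island/element intervals.

## Clonal structure

The concatenated-SNP alignment (plus the reference row) is exported as
FASTA and relaxed PHYLIP for external maximum-likelihood or
recombination-aware tools — those inferences are deliberately delegated,
not reimplemented. The built-in tree is neighbor joining on pairwise
Hamming distances over SNP columns (per-site corrections are negligible at
these divergences), with genome ids sorted before the join for
deterministic tie-breaking, rooted on the reference row as the ancestral
stand-in. Clades are *maximal monophyletic groups supported by ≥ 1 allele
fixed within and absent outside the group* (support = count of such
alleles); genomes in no supported group become singleton clades. This is
an allele-based criterion, distinct from bootstrap support; labels are
ordered by clade size then smallest member id, so they are invariant to
input order.

## The simulator: what it emulates, and what it does not

Defaults are the study conditions: 47 genomes in 7 clades (sizes
6,6,5,5,5,2,18 — five clades in the larger spring, two in the smaller),
119 core SNPs = 19 clade-fixed (2,2,2,2,2,3,6 per clade) + 17 private
(3,3,3,3,2,0,3) + 83 singletons (0–10 per genome in the first spring's
clades, 0–4 in the second's), 21 insertions + 10 deletions of 1–10 bp and
4 multi-base substitutions, one 33 kb island with six nested deletion
patterns (intact; two deletions shared across two clades; one deletion in
a third clade; one clade-specific deletion; one full-island loss; one
private deletion), two plasmid-like (30 kb, 35 kb) and one virus-like
(17 kb) integrated element with clade-correlated carrier sets, and four
CRISPR arrays (24 bp repeat, eight 38 bp spacers) identical across all
genomes. A clade of size 2 cannot carry a private non-fixed allele
(private needs ≥ 2 carriers forming a proper subset), so the unique
alleles distinguishing such a clade are planted as clade-fixed. The default
reference is 500 kb rather than ~2.2 Mb — the variant *counts* (not
densities) are what the recovery analyses consume, and the scaled genome
keeps a full pipeline run around a minute; per-bp divergence on the
default simulation is correspondingly ~4× the real-data scale.

Planting rules that matter for exact-recovery testing: edits keep ≥ 50 bp
spacing (the real SNP density is ~1 per 17 kb, so this is generous);
indels and substitutions are drawn left-normalisation-stable (content
re-sampled otherwise), so planted records equal canonical call
representations; elements get GC +0.05 relative to the reference so
presence verification is non-trivial; genes are tiled from sense codons
only (no internal stops); planted protospacers copy real spacers into the
virus, a plasmid, and a deleted island segment. Reads have uniform starts
and uniform substitution errors only — no indel errors, no quality model,
no coverage bias, no paired ends.

Consequently, passing the recovery suite shows the pipeline is *correct
under its stated assumptions* (collinear near-identical assemblies,
unambiguous anchoring, error-free or error-light reads); it does not show
robustness to misassembly, rearrangement, repeat-dense references,
recombination, or real sequencing artifacts — the single-genome island
filter exists precisely because real data contain misassemblies, but the
simulator does not emulate them.

## Determinism

Identical (config, seed) yields byte-identical genomes, reads and truth
tables. The simulator's internal stream is a child of the seed with a
distinct spawn key from the reference generator's stream, so planted
features never echo reference bases (a same-seed replay would otherwise
make the first CRISPR repeat duplicate the reference's first bases). All
tie-breaks (anchor chaining, NJ joins, pattern and clade labels) are
explicit and order-independent.

## Problem sizes used in checks

The default full-scale analyses (47 genomes × 500 kb, with reads at 30× /
100 bp over the 33 kb island) run in roughly a minute; unit analyses use
8–10 genomes on 60–100 kb references. Oracle comparisons run the full DP
alignment on 3–4 kb pairs, the per-base island scan on 50 kb toys,
Tajima's D re-derivation for n ∈ [4, 10], and exhaustive 9-change codon
enumeration on 200–300-codon genes.
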