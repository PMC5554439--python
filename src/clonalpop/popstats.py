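"""Population-genetic statistics on the core SNP matrix.

Allele classification (singleton / private / shared, with fixed-vs-reference
and fixed-within-clade flags), core-genome divergence, Tajima's D from the
standard constants, Nei-Gojobori potential-site counting with per-SNP
synonymous/nonsynonymous classification under genetic code 11, dn/ds as a
ratio of proportions (no distance correction: at divergences of ~1e-5 the
correction is far below the printed precision), and the multi-hit gene
report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._kmer import revcomp
from .core import SmallVariant, SnpMatrix

_CODE_TABLE = CodonTable.unambiguous_dna_by_id[11]


# ---------------------------------------------------------------------------
# allele classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteClass:
    position: int
    carriers: tuple[str, ...]
    biallelic: bool
    klass: str  # singleton | private | shared
    fixed_vs_reference: bool
    fixed_in_clade: str | None  # clade label if carriers == that whole clade


@dataclass
class AlleleClassification:
    sites: list[SiteClass]
    fixed_per_clade: dict[str, int]  # unique fixed-SNP count per clade

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.sites:
            out[s.klass] = out.get(s.klass, 0) + 1
        return out

    def singletons_per_genome(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.sites:
            if s.klass == "singleton":
                g = s.carriers[0]
                out[g] = out.get(g, 0) + 1
        return out


def classify_alleles(matrix: SnpMatrix, clades: dict[str, str]) -> AlleleClassification:
    """Classify every site of the matrix by its carrier set.

    singleton: one carrier; private: >=2 carriers all in one clade (flagged
    fixed_in_clade when they are the whole clade); shared: carriers span
    clades. fixed_vs_reference flags sites where every genome differs from
    the reference. Sites with more than one alternative allele are flagged
    non-biallelic and excluded from the private tally (but remain in the
    matrix for S and pi).
    """
    missing = [g for g in matrix.genomes if g not in clades]
    if missing:
        raise KeyError(f"genomes missing from clade map: {missing}")
    members: dict[str, set[str]] = {}
    for g, c in clades.items():
        if g in matrix.genomes:
            members.setdefault(c, set()).add(g)

    sites: list[SiteClass] = []
    fixed_per_clade = {c: 0 for c in members}
    for j in range(matrix.n_sites):
        col = matrix.alleles[:, j]
        carriers = matrix.carriers(j)
        alt_alleles = {a for a, g in zip(col, matrix.genomes) if a != matrix.ref_alleles[j]}
        biallelic = len(alt_alleles) == 1
        carrier_clades = {clades[g] for g in carriers}
        fixed_vs_ref = len(carriers) == len(matrix.genomes)
        if len(carriers) == 1:
            klass = "singleton"
        elif len(carrier_clades) == 1 and biallelic:
            klass = "private"
        else:
            klass = "shared"
        fixed_in = None
        if len(carrier_clades) == 1:
            clade = next(iter(carrier_clades))
            if set(carriers) == members[clade]:
                fixed_in = clade
                if klass == "private":
                    fixed_per_clade[clade] += 1
        sites.append(
            SiteClass(
                int(matrix.positions[j]), carriers, biallelic, klass, fixed_vs_ref, fixed_in
            )
        )
    return AlleleClassification(sites, fixed_per_clade)


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergenceStats:
    polymorphisms: int
    core_length: int
    d_total: float  # polymorphism count / core length
    d_pi: float  # mean pairwise difference count / core length


def mean_pairwise_differences(matrix: SnpMatrix, genomes: Sequence[str] | None = None) -> float:
    """Mean number of differing SNP columns over all genome pairs."""
    if genomes is None:
        rows = matrix.alleles
    else:
        idx = [matrix.genomes.index(g) for g in genomes]
        rows = matrix.alleles[idx]
    n = rows.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    if rows.shape[1] == 0:
        return 0.0
    for j in range(rows.shape[1]):
        _, counts = np.unique(rows[:, j], return_counts=True)
        total += (n * n - np.sum(counts**2)) / 2.0
    return total / (n * (n - 1) / 2.0)


def divergence(matrix: SnpMatrix, core_length: int) -> DivergenceStats:
    """Core-genome divergence: total (P / L) and mean-pairwise (pi / L)."""
    if core_length <= 0:
        raise ValueError("core_length must be > 0")
    P = matrix.n_sites
    pi = mean_pairwise_differences(matrix)
    return DivergenceStats(P, core_length, P / core_length, pi / core_length)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajimas_d(n: int, s: int, pi: float) -> float:
    """Tajima's D from sequence count n, segregating sites S, and mean
    pairwise differences pi (per alignment, not per site).

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard constants.
    Raises ValueError when S = 0 (the statistic is undefined, not zero).
    """
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if s < 1:
        raise ValueError("Tajima's D is undefined for S = 0")
    if pi < 0:
        raise ValueError("pi must be >= 0")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def tajimas_d_from_matrix(matrix: SnpMatrix, genomes: Sequence[str] | None = None) -> float | None:
    """D over the concatenated core SNP columns for a genome subset.

    Monomorphic-within-subset columns contribute nothing to S or pi.
    Returns None when fewer than 4 genomes or no segregating site.
    """
    ids = list(genomes) if genomes is not None else list(matrix.genomes)
    if len(ids) < 4:
        return None
    idx = [matrix.genomes.index(g) for g in ids]
    rows = matrix.alleles[idx]
    seg = 0
    for j in range(rows.shape[1]):
        if len(set(rows[:, j])) > 1:
            seg += 1
    if seg == 0:
        return None
    pi = mean_pairwise_differences(matrix, ids)
    return tajimas_d(len(ids), seg, pi)


# ---------------------------------------------------------------------------
# Nei-Gojobori site counting and dn/ds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpEffect:
    position: int
    gene: str | None
    effect: str  # synonymous | nonsynonymous | nonsense | intergenic


@dataclass
class CodingEffects:
    n_sites: float  # potential nonsynonymous sites
    s_sites: float  # potential synonymous sites
    effects: list[SnpEffect]
    per_gene: pd.DataFrame  # index gene, columns syn/nonsyn/indel

    def observed(self) -> tuple[int, int]:
        n_obs = sum(1 for e in self.effects if e.effect in ("nonsynonymous", "nonsense"))
        s_obs = sum(1 for e in self.effects if e.effect == "synonymous")
        return n_obs, s_obs


def codon_synonymous_fraction(codon: str) -> list[float]:
    """Per-position fraction of the 3 single-base changes that are synonymous."""
    aa = _translate(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} in reference frame")
    out = []
    for i in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if _translate(alt) == aa:
                syn += 1
        out.append(syn / 3.0)
    return out


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def coding_effects(
    matrix: SnpMatrix,
    genes: Sequence[tuple[str, int, int, str]],
    reference: str,
    indels: Sequence[SmallVariant] = (),
) -> CodingEffects:
    """Potential syn/nonsyn sites over all genes and the effect of each SNP.

    ``genes`` rows are (gene_id, start, end, strand) on the reference,
    0-based half-open, length divisible by 3, stop-free in frame. Every
    change to a stop codon counts as nonsynonymous (flagged nonsense), so
    N_sites + S_sites = 3 x codon count exactly.
    """
    n_sites = 0.0
    s_sites = 0.0
    gene_rows: dict[str, dict[str, int]] = {}
    gene_lookup: list[tuple[int, int, str, str]] = []
    for gid, start, end, strand in genes:
        if (end - start) % 3 != 0:
            raise ValueError(f"gene {gid} length not divisible by 3")
        seq = reference[start:end]
        coding = seq if strand == "+" else revcomp(seq)
        for ci in range(0, len(coding), 3):
            fracs = codon_synonymous_fraction(coding[ci : ci + 3])
            s_sites += sum(fracs)
            n_sites += 3 - sum(fracs)
        gene_rows[gid] = {"syn": 0, "nonsyn": 0, "indel": 0}
        gene_lookup.append((start, end, strand, gid))
    gene_lookup.sort()

    def locate(pos: int):
        for start, end, strand, gid in gene_lookup:
            if start <= pos < end:
                return start, end, strand, gid
        return None

    effects: list[SnpEffect] = []
    for j in range(matrix.n_sites):
        pos = int(matrix.positions[j])
        alts = sorted({a for a in matrix.alleles[:, j] if a != matrix.ref_alleles[j]})
        hit = locate(pos)
        if hit is None:
            effects.append(SnpEffect(pos, None, "intergenic"))
            continue
        start, end, strand, gid = hit
        for alt in alts:
            effect = _snp_effect(reference, start, end, strand, pos, alt)
            effects.append(SnpEffect(pos, gid, effect))
            key = "syn" if effect == "synonymous" else "nonsyn"
            gene_rows[gid][key] += 1
    for v in indels:
        if v.type not in ("insertion", "deletion"):
            continue
        hit = locate(v.position)
        if hit is not None:
            gene_rows[hit[3]]["indel"] += 1

    per_gene = pd.DataFrame.from_dict(gene_rows, orient="index")
    per_gene.index.name = "gene"
    return CodingEffects(n_sites, s_sites, effects, per_gene)


def _snp_effect(reference, start, end, strand, pos, alt) -> str:
    seq = reference[start:end]
    off = pos - start
    if strand == "-":
        coding = revcomp(seq)
        off = (end - start) - 1 - off
        alt = revcomp(alt)
    else:
        coding = seq
    ci = off // 3 * 3
    codon = coding[ci : ci + 3]
    mutant = codon[: off % 3] + alt + codon[off % 3 + 1 :]
    aa0, aa1 = _translate(codon), _translate(mutant)
    if aa1 == "*":
        return "nonsense"
    return "synonymous" if aa0 == aa1 else "nonsynonymous"


def dnds(n_obs: int, s_obs: int, n_sites: float, s_sites: float) -> float:
    """(N_obs/N_sites) / (S_obs/S_sites), proportions without correction."""
    if min(n_obs, s_obs) < 0:
        raise ValueError("observed counts must be >= 0")
    if n_sites <= 0 or s_sites <= 0:
        raise ValueError("site counts must be > 0")
    if s_obs == 0:
        raise ValueError("dn/ds undefined when no synonymous changes observed")
    return (n_obs / n_sites) / (s_obs / s_sites)


# ---------------------------------------------------------------------------
# multi-hit genes
# ---------------------------------------------------------------------------


def multi_hit_genes(
    effects: CodingEffects,
    classification: AlleleClassification,
    indels: Sequence[SmallVariant] = (),
    genes: Sequence[tuple[str, int, int, str]] = (),
) -> pd.DataFrame:
    """Genes with >= 2 mutations, with (syn, nonsyn, indel) tallies.

    Partitioned into 'fixed_vs_reference' (every study genome carries the
    change) and 'variable' (polymorphic within the population).
    """
    fixed_positions = {s.position for s in classification.sites if s.fixed_vs_reference}
    gene_lookup = sorted((start, end, gid) for gid, start, end, _ in genes)

    def locate(pos: int):
        for start, end, gid in gene_lookup:
            if start <= pos < end:
                return gid
        return None

    rows: dict[tuple[str, str], dict[str, int]] = {}

    def bump(gene: str, partition: str, key: str):
        r = rows.setdefault((gene, partition), {"syn": 0, "nonsyn": 0, "indel": 0})
        r[key] += 1

    for e in effects.effects:
        if e.gene is None:
            continue
        partition = "fixed_vs_reference" if e.position in fixed_positions else "variable"
        bump(e.gene, partition, "syn" if e.effect == "synonymous" else "nonsyn")
    n_genomes = len({g for s in classification.sites for g in s.carriers}) or 1
    for v in indels:
        if v.type not in ("insertion", "deletion"):
            continue
        gid = locate(v.position)
        if gid is not None:
            bump(gid, "variable", "indel")

    records = []
    for (gene, partition), tallies in rows.items():
        if sum(tallies.values()) >= 2:
            records.append({"gene": gene, "partition": partition, **tallies})
    df = pd.DataFrame(records, columns=["gene", "partition", "syn", "nonsyn", "indel"])
    return df.sort_values(["partition", "gene"]).reset_index(drop=True)
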