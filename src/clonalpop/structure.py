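"""Concatenated-SNP alignment, distance-based clade inference, and the
integrated per-run report.

The clonal phylogeny is a neighbor-joining tree on pairwise Hamming
distances over SNP columns (per-site corrections are negligible at
divergences of ~1e-5), rooted on the reference row, which stands in for the
ancestral strain. Clades are operationalized as maximal monophyletic groups
supported by at least ``min_support`` alleles fixed within and absent
outside the group; maximum-likelihood and recombination-aware tree
inference are intentionally delegated to external tools via the exported
alignments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from io import StringIO
from typing import Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .core import SnpMatrix

REF_LABEL = "REF"


@dataclass
class CladeAssignment:
    clade_of: dict[str, str]  # genome -> clade label
    support: dict[str, int]  # clade -> count of private fixed alleles

    def members(self, clade: str) -> list[str]:
        return sorted(g for g, c in self.clade_of.items() if c == clade)

    def partition(self) -> set[frozenset]:
        out: dict[str, set] = {}
        for g, c in self.clade_of.items():
            out.setdefault(c, set()).add(g)
        return {frozenset(v) for v in out.values()}


def concat_snp_alignment(matrix: SnpMatrix, include_reference: bool = True) -> MultipleSeqAlignment:
    """One aligned sequence per genome over SNP columns, plus the reference row."""
    if matrix.n_sites < 1 or len(matrix.genomes) < 2:
        raise ValueError("need >= 2 genomes and >= 1 site")
    records = []
    if include_reference:
        records.append(SeqRecord(Seq("".join(matrix.ref_alleles)), id=REF_LABEL, description=""))
    for i, g in enumerate(matrix.genomes):
        records.append(SeqRecord(Seq("".join(matrix.alleles[i])), id=g, description=""))
    return MultipleSeqAlignment(records)


def write_alignment(alignment: MultipleSeqAlignment, fasta_path=None, phylip_path=None) -> None:
    if fasta_path is not None:
        AlignIO.write(alignment, str(fasta_path), "fasta")
    if phylip_path is not None:
        AlignIO.write(alignment, str(phylip_path), "phylip-relaxed")


def hamming_matrix(matrix: SnpMatrix, include_reference: bool = True):
    """Pairwise count of differing SNP columns (no per-site model)."""
    labels = ([REF_LABEL] if include_reference else []) + sorted(matrix.genomes)
    rows = []
    for label in labels:
        if label == REF_LABEL:
            rows.append(matrix.ref_alleles)
        else:
            rows.append(matrix.alleles[matrix.genomes.index(label)])
    arr = np.array(rows)
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.count_nonzero(arr[i] != arr[j]))
            dm[i, j] = dm[j, i] = d
    return labels, dm


def nj_tree(matrix: SnpMatrix, root_on: str = REF_LABEL) -> TreeNode:
    """Neighbor-joining tree over SNP-column Hamming distances.

    Genome ids are sorted before the join (deterministic tie-breaking);
    the tree is rooted on ``root_on`` (default: the reference row, the
    ancestral stand-in).
    """
    if len(matrix.genomes) < 3:
        raise ValueError("need >= 3 genomes")
    labels, dm = hamming_matrix(matrix, include_reference=True)
    tree = nj(DistanceMatrix(dm, labels))
    ref_tip = tree.find(root_on)
    rooted = tree.root_at(ref_tip.parent, reset=True)
    return rooted


def assign_clades(
    matrix: SnpMatrix, tree: TreeNode, min_support: int = 1
) -> CladeAssignment:
    """Maximal monophyletic groups supported by private fixed alleles.

    A node's support is the number of SNP columns whose carrier set equals
    exactly the node's genome set. Nodes are accepted root-down, skipping
    descendants of accepted nodes; unassigned genomes become singleton
    clades. Labels are ordered by descending clade size, then smallest
    member id.
    """
    tip_names = {t.name for t in tree.tips()} - {REF_LABEL}
    if tip_names != set(matrix.genomes):
        raise ValueError("tree leaves do not match matrix genomes")
    carrier_sets: dict[frozenset, int] = {}
    for j in range(matrix.n_sites):
        key = frozenset(matrix.carriers(j))
        carrier_sets[key] = carrier_sets.get(key, 0) + 1

    all_genomes = frozenset(matrix.genomes)
    accepted: list[tuple[frozenset, int]] = []

    def walk(node):
        leaves = frozenset(t.name for t in node.tips()) - {REF_LABEL}
        if node.is_tip():
            leaves = frozenset({node.name} if node.name != REF_LABEL else set())
        if leaves and leaves != all_genomes:
            support = carrier_sets.get(leaves, 0)
            if support >= min_support:
                accepted.append((leaves, support))
                return
        for child in node.children:
            walk(child)

    walk(tree)
    assigned = set().union(*[set(c) for c, _ in accepted]) if accepted else set()
    for g in sorted(all_genomes - assigned):
        accepted.append((frozenset({g}), 0))
    accepted.sort(key=lambda cs: (-len(cs[0]), min(cs[0])))
    clade_of, support = {}, {}
    for i, (members, sup) in enumerate(accepted, start=1):
        label = f"clade{i}"
        support[label] = sup
        for g in members:
            clade_of[g] = label
    return CladeAssignment(clade_of, support)


def population_report(
    clades: CladeAssignment,
    divergence_stats=None,
    tajima_overall: float | None = None,
    tajima_by_clade: dict[str, float | None] | None = None,
    classification=None,
    regions: Sequence | None = None,
    patterns: dict[str, str] | None = None,
    array_counts: dict[str, int] | None = None,
) -> dict:
    """Joined JSON-serializable run summary (clades x islands x statistics)."""
    report: dict = {"clades": {}}
    for clade in sorted(clades.support, key=lambda c: int(c.replace("clade", ""))):
        members = clades.members(clade)
        entry = {"members": members, "private_fixed_support": clades.support[clade]}
        if tajima_by_clade is not None:
            entry["tajimas_d"] = tajima_by_clade.get(clade)
        if regions is not None:
            entry["island_presence"] = {
                r.region_id: sum(1 for g in members if r.presence.get(g, False))
                for r in regions
            }
        if patterns is not None:
            entry["deletion_patterns"] = sorted({patterns[g] for g in members if g in patterns})
        report["clades"][clade] = entry
    if divergence_stats is not None:
        report["divergence"] = {
            "polymorphisms": divergence_stats.polymorphisms,
            "core_length": divergence_stats.core_length,
            "d_total": divergence_stats.d_total,
            "d_pi": divergence_stats.d_pi,
        }
    if tajima_overall is not None:
        report["tajimas_d_overall"] = tajima_overall
    if classification is not None:
        report["allele_classes"] = classification.counts()
        report["fixed_per_clade"] = classification.fixed_per_clade
    if array_counts is not None:
        report["crispr_arrays_per_genome"] = array_counts
    return report


def render_report(report: dict) -> str:
    return json.dumps(report, indent=2, default=float)


def tree_to_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
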