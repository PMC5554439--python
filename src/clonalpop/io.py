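"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython; the tabular outputs (VCF-like variant table,
BED intervals, bedGraph coverage, presence/absence matrix, GFF3 features)
are plain text with the conventional column layouts. Interval coordinates
are 0-based half-open internally; 1-based closed in VCF-like and GFF3 output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_gff3(path, seqid: str, features: Iterable[tuple[str, int, int, str, str]]) -> None:
    """Write (feature_id, start, end, strand, type) rows; input 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for fid, start, end, strand, ftype in features:
            fh.write(
                f"{seqid}\tclonalpop\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t0\t"
                f"ID={fid}\n"
            )


def read_gff3_genes(path) -> list[tuple[str, int, int, str]]:
    """(gene_id, start, end, strand) rows, 0-based half-open, type 'gene' or 'CDS'."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] not in ("gene", "CDS"):
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            out.append((attrs.get("ID", cols[8]), int(cols[3]) - 1, int(cols[4]), cols[6]))
    return out


def write_variants_tsv(path, variants, chrom: str = "REF") -> None:
    """VCF-like TSV: CHROM, POS (1-based), REF, ALT, TYPE, GENOME, LENGTH."""
    rows = [
        {
            "CHROM": chrom,
            "POS": v.position + 1,
            "REF": v.ref_allele or ".",
            "ALT": v.alt_allele or ".",
            "TYPE": v.type,
            "GENOME": v.genome,
            "LENGTH": v.length,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed(path, intervals: Iterable[tuple[int, int, str]], chrom: str = "REF") -> None:
    with open(path, "w") as fh:
        for start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_bedgraph(path, depth, chrom: str) -> None:
    """Per-base depth vector as run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[start]:
                fh.write(f"{chrom}\t{start}\t{i}\t{int(depth[start])}\n")
                start = i


def write_presence_matrix(path, presence: dict[str, dict[str, bool]]) -> None:
    """Islands/regions x genomes 0/1 TSV (rows: region id)."""
    df = pd.DataFrame(presence).T.astype(int)
    df.index.name = "region"
    df.to_csv(path, sep="\t")


def write_snp_matrix_tsv(path, matrix) -> None:
    df = matrix.to_frame()
    df.to_csv(path, sep="\t")


def read_snp_matrix_tsv(path):
    from .core import SnpMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    positions = [int(c) for c in df.columns]
    ref_alleles = [str(b) for b in df.loc["REF"]]
    genomes = [g for g in df.index if g != "REF"]
    alleles = {g: "".join(df.loc[g]) for g in genomes}
    return SnpMatrix.from_alleles(positions, ref_alleles, alleles)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
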