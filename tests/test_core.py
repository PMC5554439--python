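"""Anchoring, small-variant calling, core blocks and the SNP matrix."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalpop.core import (
    apply_variants,
    build_snp_matrix,
    call_small_variants,
    concat_scaffolds,
    extract_core_blocks,
    find_anchors,
    left_normalize,
)
from clonalpop.simulate import generate_reference

from .conftest import small_config


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def full_dp_variants(reference: str, query: str):
    """Independent oracle: full global affine-gap DP alignment of the whole
    pair, decoded column-by-column from the gapped strings."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    aln = aligner.align(reference, query)[0]
    gapped_ref, gapped_q = str(aln[0]), str(aln[1])
    out = set()
    rpos = 0
    run = None  # (kind, start_rpos, ref_part, q_part)

    def flush(run):
        if run is None:
            return
        kind, start, rpart, qpart = run
        if kind == "mm":
            vtype = "snp" if len(rpart) == 1 else "substitution"
            out.add((vtype, start, rpart, qpart))
        elif kind == "del":
            p, r, a = left_normalize(reference, start, rpart, "")
            out.add(("deletion", p, r, a))
        else:
            p, r, a = left_normalize(reference, start, "", qpart)
            out.add(("insertion", p, r, a))

    for rc, qc in zip(gapped_ref, gapped_q):
        if rc == "-":
            kind = "ins"
        elif qc == "-":
            kind = "del"
        elif rc != qc:
            kind = "mm"
        else:
            kind = None
        if kind is None:
            flush(run)
            run = None
        elif run is not None and run[0] == kind:
            run = (kind, run[1], run[2] + (rc if rc != "-" else ""), run[3] + (qc if qc != "-" else ""))
        else:
            flush(run)
            run = (kind, rpos, rc if rc != "-" else "", qc if qc != "-" else "")
        if rc != "-":
            rpos += 1
    flush(run)
    return out


class TestFindAnchors:
    def test_identical_pair_single_anchor(self):
        ref = generate_reference(10_000, 0.5, seed=3).seq
        chain = find_anchors(ref, ref)
        assert len(chain.anchors) == 1
        a = chain.anchors[0]
        assert (a.ref_start, a.ref_end, a.query_start, a.query_end) == (0, 10_000, 0, 10_000)

    def test_single_snp_splits_into_two_abutting_anchors(self):
        ref = generate_reference(10_000, 0.5, seed=3).seq
        p = 5000
        alt = "A" if ref[p] != "A" else "C"
        query = ref[:p] + alt + ref[p + 1 :]
        chain = find_anchors(ref, query)
        assert len(chain.anchors) == 2
        assert chain.anchors[0].ref_end == p
        assert chain.anchors[1].ref_start == p + 1

    def test_gaps_at_planted_coordinates(self, rng):
        ref = _random_seq(rng, 100_000)
        # 10 SNPs + one 2 kb deletion
        snp_pos = sorted(rng.choice(np.arange(1000, 60_000, 100), 10, replace=False))
        query = list(ref)
        for p in snp_pos:
            query[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[p]]
        del_start = 70_000
        query = "".join(query[:del_start] + query[del_start + 2000 :])
        chain = find_anchors(ref, query)
        gap_refs = {rs for rs, re, qs, qe in chain.gaps()}
        for p in snp_pos:
            assert int(p) in gap_refs
        big = [(rs, re) for rs, re, qs, qe in chain.gaps() if re - rs > 100]
        assert len(big) == 1
        assert abs(big[0][0] - del_start) <= 30 and abs(big[0][1] - (del_start + 2000)) <= 30

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_anchors("", "ACGT" * 100)

    def test_scaffold_spacer_never_anchors(self):
        ref = generate_reference(5000, 0.5, seed=9).seq
        query = concat_scaffolds([ref[:2000], ref[2000:]])
        chain = find_anchors(ref, query)
        joined = "".join(
            query[a.query_start : a.query_end] for a in chain.anchors
        )
        assert "N" not in joined


class TestCallSmallVariants:
    def test_identical_pair_no_variants(self):
        ref = generate_reference(5000, 0.5, seed=4).seq
        chain = find_anchors(ref, ref)
        assert call_small_variants(ref, ref, chain) == []

    def test_single_snp_called_exactly(self):
        ref = generate_reference(5000, 0.5, seed=4).seq
        p = 2500
        alt = "G" if ref[p] != "G" else "T"
        query = ref[:p] + alt + ref[p + 1 :]
        chain = find_anchors(ref, query)
        calls = call_small_variants(ref, query, chain)
        assert [(v.position, v.type, v.ref_allele, v.alt_allele) for v in calls] == [
            (p, "snp", ref[p], alt)
        ]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_applying_calls_reconstructs_query(self, seed):
        """Property: anchored calls applied to the reference rebuild the query."""
        rng = np.random.default_rng(seed)
        ref = _random_seq(rng, 8000)
        query, _ = _plant_random_edits(rng, ref)
        chain = find_anchors(ref, query)
        calls = call_small_variants(ref, query, chain)
        assert apply_variants(ref, calls) == query

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_full_dp_alignment(self, seed):
        """Calls equal a full affine-gap dynamic-programming global alignment."""
        rng = np.random.default_rng(seed)
        ref = _random_seq(rng, 3000)
        # snp/ins/del only: multi-base substitutions can tie with gapped
        # decompositions under any scoring, making the optimum non-unique
        query, _ = _plant_random_edits(
            rng, ref, n_edits=8, spacing=120, kinds=("snp", "insertion", "deletion")
        )
        chain = find_anchors(ref, query)
        calls = {
            (v.type, v.position, v.ref_allele, v.alt_allele)
            for v in call_small_variants(ref, query, chain)
        }
        assert calls == full_dp_variants(ref, query)

    @pytest.mark.parametrize("seed", range(4))
    def test_planted_edit_set_recovered_at_scale(self, seed):
        """At 18 kb with 30 mixed edits: the call set equals the planted set,
        the query is reconstructed, and the spent edit cost is never below
        the true minimal (edlib) edit distance."""
        rng = np.random.default_rng(100 + seed)
        ref = _random_seq(rng, 18_000)
        query, edits = _plant_random_edits(rng, ref, n_edits=30)
        chain = find_anchors(ref, query)
        calls = call_small_variants(ref, query, chain)
        assert apply_variants(ref, calls) == query
        expected = set()
        for p, rl, alt in edits:
            if rl == 0:
                expected.add(("insertion", p, "", alt))
            elif alt == "":
                expected.add(("deletion", p, ref[p : p + rl], ""))
            elif rl == 1:
                expected.add(("snp", p, ref[p], alt))
            else:
                expected.add(("substitution", p, ref[p : p + rl], alt))
        got = {(v.type, v.position, v.ref_allele, v.alt_allele) for v in calls}
        assert got == expected
        cost = sum(max(len(v.ref_allele), len(v.alt_allele)) for v in calls)
        assert cost >= edlib.align(query, ref, mode="NW")["editDistance"]


def _plant_random_edits(rng, ref, n_edits=12, spacing=60, kinds=("snp", "insertion", "deletion", "substitution")):
    """Random left-stable SNPs/indels/substitutions with safe spacing."""
    positions = np.sort(rng.choice(np.arange(500, len(ref) - 500, spacing), n_edits, replace=False))
    edits = []
    for p in positions:
        p = int(p)
        kind = rng.choice(list(kinds))
        if kind == "snp":
            alt = "ACGT"[(("ACGT".index(ref[p])) + 1 + int(rng.integers(3))) % 4]
            edits.append((p, 1, alt))
        elif kind == "substitution":
            length = int(rng.integers(2, 8))
            alt = "".join(
                "ACGT"[("ACGT".index(ref[p + j]) + 1 + int(rng.integers(3))) % 4]
                for j in range(length)
            )
            edits.append((p, length, alt))
        elif kind == "deletion":
            length = int(rng.integers(1, 8))
            if ref[p - 1] == ref[p + length - 1]:
                continue  # not left-stable; skip
            edits.append((p, length, ""))
        else:
            length = int(rng.integers(1, 8))
            ins = _random_seq(rng, length)
            if ins[-1] == ref[p - 1]:
                continue
            edits.append((p, 0, ins))
    out, prev = [], 0
    for p, rl, alt in edits:
        out.append(ref[prev:p])
        out.append(alt)
        prev = p + rl
    out.append(ref[prev:])
    return "".join(out), edits


class TestCoreBlocks:
    def test_identical_genomes_one_whole_genome_block(self):
        ref = generate_reference(5000, 0.5, seed=6).seq
        chains = [find_anchors(ref, ref, genome=f"g{i}") for i in range(3)]
        blocks = extract_core_blocks(chains, len(ref))
        assert len(blocks) == 1
        assert (blocks[0].ref_start, blocks[0].ref_end) == (0, 5000)

    def test_island_excluded_from_core(self):
        ref = generate_reference(40_000, 0.5, seed=6).seq
        query = ref[:10_000] + ref[15_000:]  # one genome missing 5 kb
        chains = [
            find_anchors(ref, ref, genome="g0"),
            find_anchors(ref, query, genome="g1"),
        ]
        blocks = extract_core_blocks(chains, len(ref))
        for b in blocks:
            assert b.ref_end <= 10_000 + 30 or b.ref_start >= 15_000 - 30

    def test_core_length_matches_truth_footprint(self, small_population, small_core):
        cfg, genomes, truth = small_population
        isl = truth.islands[0]
        expected = len(truth.reference) - (isl.end - isl.start)
        # +- 500 bp per junction
        assert abs(small_core.core_length - expected) <= 1000

    def test_needs_two_genomes(self):
        with pytest.raises(ValueError):
            extract_core_blocks([], 1000)


class TestSnpMatrix:
    def test_no_variants_empty_matrix(self):
        ref = generate_reference(2000, 0.5, seed=7).seq
        m = build_snp_matrix({"a": [], "b": []}, [], ref)
        assert m.n_sites == 0

    def test_shared_snp_single_column(self):
        ref = generate_reference(2000, 0.5, seed=7).seq
        from clonalpop.core import CoreBlock, SmallVariant

        p = 1000
        alt = "A" if ref[p] != "A" else "T"
        v = SmallVariant("g1", p, "snp", ref[p], alt)
        w = SmallVariant("g2", p, "snp", ref[p], alt)
        m = build_snp_matrix({"g1": [v], "g2": [w], "g3": []}, [CoreBlock(0, 2000)], ref)
        assert m.n_sites == 1
        assert m.carriers(0) == ("g1", "g2")
        assert m.row("g3") == ref[p]

    def test_conflicting_alleles_rejected(self):
        ref = "ACGT" * 500
        from clonalpop.core import CoreBlock, SmallVariant

        vs = [
            SmallVariant("g1", 100, "snp", ref[100], "G"),
            SmallVariant("g1", 100, "snp", ref[100], "T"),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            build_snp_matrix({"g1": vs, "g2": []}, [CoreBlock(0, 2000)], ref)

    def test_matrix_recovery_equals_truth(self, small_population, small_core):
        cfg, genomes, truth = small_population
        m = small_core.matrix
        truth_set = {(r.position, r.ref, r.alt, tuple(r.carriers)) for r in truth.snps}
        got = set()
        for j in range(m.n_sites):
            carr = m.carriers(j)
            alts = {str(m.alleles[m.genomes.index(g), j]) for g in carr}
            assert len(alts) == 1
            got.add((int(m.positions[j]), str(m.ref_alleles[j]), alts.pop(), carr))
        assert got == truth_set

    def test_query_role_symmetry(self):
        """Swapping which identical genome is query leaves the matrix unchanged."""
        ref = generate_reference(5000, 0.5, seed=8).seq
        p = 2400
        alt = "C" if ref[p] != "C" else "A"
        mut = ref[:p] + alt + ref[p + 1 :]
        chains_a = {g: find_anchors(ref, s, genome=g) for g, s in [("x", mut), ("y", mut)]}
        va = {g: call_small_variants(ref, mut, c) for g, c in chains_a.items()}
        blocks = extract_core_blocks(list(chains_a.values()), len(ref))
        m1 = build_snp_matrix(va, blocks, ref)
        m2 = build_snp_matrix(dict(reversed(list(va.items()))), blocks, ref)
        assert m1.carriers(0) == tuple(sorted(m2.carriers(0)))


class TestLeftNormalize:
    def test_deletion_shifts_left_through_repeat(self):
        ref = "ACGTTTTTACGT"
        # deleting any single T is equivalent; canonical is the leftmost
        p, r, a = left_normalize(ref, 7, "T", "")
        assert (p, r, a) == (3, "T", "")

    def test_insertion_shifts_left(self):
        ref = "ACGTTTTTACGT"
        p, r, a = left_normalize(ref, 8, "", "T")
        assert (p, r, a) == (3, "", "T")

    def test_snp_untouched(self):
        assert left_normalize("AAAA", 2, "A", "G") == (2, "A", "G")
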