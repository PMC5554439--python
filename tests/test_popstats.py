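"""Allele classification, divergence, Tajima's D, Nei-Gojobori, dn/ds."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from clonalpop.core import SnpMatrix
from clonalpop.popstats import (
    classify_alleles,
    coding_effects,
    codon_synonymous_fraction,
    divergence,
    dnds,
    mean_pairwise_differences,
    multi_hit_genes,
    tajimas_d,
    tajimas_d_from_matrix,
)


def matrix_from_rows(rows: dict[str, str], ref: str, positions=None):
    positions = positions or list(range(len(ref)))
    return SnpMatrix.from_alleles(positions, list(ref), rows)


class TestClassifyAlleles:
    CLADES = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}

    def test_single_carrier_is_singleton(self):
        m = matrix_from_rows(
            {"a1": "T", "a2": "C", "a3": "C", "b1": "C", "b2": "C"}, "C"
        )
        cl = classify_alleles(m, self.CLADES)
        assert cl.sites[0].klass == "singleton"
        assert cl.sites[0].carriers == ("a1",)

    def test_whole_clade_is_private_and_fixed(self):
        m = matrix_from_rows(
            {"a1": "T", "a2": "T", "a3": "T", "b1": "C", "b2": "C"}, "C"
        )
        cl = classify_alleles(m, self.CLADES)
        assert cl.sites[0].klass == "private"
        assert cl.sites[0].fixed_in_clade == "A"
        assert cl.fixed_per_clade["A"] == 1

    def test_cross_clade_is_shared(self):
        m = matrix_from_rows(
            {"a1": "T", "a2": "C", "a3": "C", "b1": "T", "b2": "C"}, "C"
        )
        cl = classify_alleles(m, self.CLADES)
        assert cl.sites[0].klass == "shared"

    def test_all_genomes_flagged_fixed_vs_reference(self):
        m = matrix_from_rows(
            {"a1": "T", "a2": "T", "a3": "T", "b1": "T", "b2": "T"}, "C"
        )
        cl = classify_alleles(m, self.CLADES)
        assert cl.sites[0].fixed_vs_reference

    def test_triallelic_excluded_from_private(self):
        m = matrix_from_rows(
            {"a1": "T", "a2": "G", "a3": "C", "b1": "C", "b2": "C"}, "C"
        )
        cl = classify_alleles(m, self.CLADES)
        assert not cl.sites[0].biallelic
        assert cl.sites[0].klass == "shared"

    def test_partition_is_exhaustive_and_exclusive(self, small_population, small_core):
        cfg, _, truth = small_population
        cl = classify_alleles(small_core.matrix, truth.clades)
        assert all(s.klass in ("singleton", "private", "shared") for s in cl.sites)
        counts = cl.counts()
        assert sum(counts.values()) == small_core.matrix.n_sites

    def test_recovers_planted_classes_exactly(self, small_population, small_core):
        cfg, _, truth = small_population
        cl = classify_alleles(small_core.matrix, truth.clades)
        planted = truth.snp_class_counts()
        counts = cl.counts()
        # planted clade_fixed alleles classify as private + fixed_in_clade
        assert counts.get("private", 0) == planted.get("clade_fixed", 0) + planted.get("private", 0)
        assert counts.get("singleton", 0) == planted.get("singleton", 0)
        fixed_per_clade_truth = {}
        for r in truth.snps:
            if r.klass == "clade_fixed":
                c = truth.clades[r.carriers[0]]
                fixed_per_clade_truth[c] = fixed_per_clade_truth.get(c, 0) + 1
        assert {c: n for c, n in cl.fixed_per_clade.items() if n} == fixed_per_clade_truth

    def test_missing_clade_label_rejected(self):
        m = matrix_from_rows({"a1": "T", "zz": "C"}, "C")
        with pytest.raises(KeyError):
            classify_alleles(m, {"a1": "A"})


class TestDivergence:
    def test_empty_matrix_zero(self):
        m = SnpMatrix.from_alleles([], [], {"g1": "", "g2": ""})
        d = divergence(m, 1000)
        assert d.d_total == 0.0 and d.d_pi == 0.0

    def test_total_is_count_over_length(self):
        rows = {f"g{i}": "T" * 119 for i in range(3)}
        m = matrix_from_rows(rows, "C" * 119, positions=list(range(119)))
        d = divergence(m, 2_000_000)
        assert d.d_total == pytest.approx(5.95e-5, rel=1e-6)

    def test_pair_divergence(self):
        # 2 genomes differing at 4 of 1000 core bp
        m = matrix_from_rows({"g1": "TTTT", "g2": "CCCC"}, "CCCC")
        d = divergence(m, 1000)
        assert d.d_pi == pytest.approx(0.004)

    def test_zero_length_rejected(self):
        m = matrix_from_rows({"g1": "T", "g2": "C"}, "C")
        with pytest.raises(ValueError):
            divergence(m, 0)


def brute_force_pi(rows: list[str]) -> float:
    pairs = list(itertools.combinations(rows, 2))
    diffs = [sum(1 for x, y in zip(a, b) if x != y) for a, b in pairs]
    return sum(diffs) / len(pairs)


def brute_force_tajima(n, s, pi):
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


class TestTajimasD:
    def test_excess_singletons_negative(self):
        n, sites = 20, 30
        # every variant a singleton spread over genomes
        pi = brute_force_pi(
            ["".join("T" if j == i % n else "C" for j in range(n)) for i in range(sites)]
        )  # not the real pi; build explicit haplotypes instead below
        rows = []
        for g in range(n):
            rows.append("".join("T" if s % n == g else "C" for s in range(sites)))
        pi = brute_force_pi(rows)
        assert tajimas_d(n, sites, pi) < 0

    def test_four_haplotypes_brute_force(self):
        haps = ["CCCC", "CTCC", "CCTA", "CCCA"]
        s = sum(1 for j in range(4) if len({h[j] for h in haps}) > 1)
        pi = brute_force_pi(haps)
        assert tajimas_d(4, s, pi) == pytest.approx(brute_force_tajima(4, s, pi), abs=1e-12)

    def test_zero_numerator_gives_zero(self):
        n, s = 10, 5
        a1 = sum(1 / i for i in range(1, n))
        assert tajimas_d(n, s, s / a1) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_for_no_segregating_sites(self):
        with pytest.raises(ValueError):
            tajimas_d(10, 0, 0.0)
        m = matrix_from_rows({"g1": "CC", "g2": "CC", "g3": "CC", "g4": "CC"}, "TT")
        assert tajimas_d_from_matrix(m) is None

    @pytest.mark.parametrize("n", range(4, 11))
    def test_oracle_equivalence_random_matrices(self, n):
        """100 random small matrices per n: D matches a from-scratch
        recomputation of pi, S and the constants to 1e-10."""
        rng = np.random.default_rng(n)
        for _ in range(100 // 7 + 3):
            sites = int(rng.integers(2, 12))
            rows = {
                f"g{i}": "".join(rng.choice(["C", "T"], size=sites)) for i in range(n)
            }
            m = matrix_from_rows(rows, "C" * sites, positions=list(range(sites)))
            seg = sum(1 for j in range(sites) if len({r[j] for r in rows.values()}) > 1)
            if seg == 0:
                continue
            pi = brute_force_pi(list(rows.values()))
            expect = brute_force_tajima(n, seg, pi)
            got = tajimas_d_from_matrix(m)
            assert got == pytest.approx(expect, abs=1e-10)


class TestNeiGojobori:
    def test_phe_third_position_fraction(self):
        fracs = codon_synonymous_fraction("TTT")
        assert fracs[2] == pytest.approx(1 / 3)  # TTT->TTC synonymous only
        assert fracs[0] == 0 and fracs[1] == 0

    def test_met_has_no_synonymous_sites(self):
        assert sum(codon_synonymous_fraction("ATG")) == 0.0

    def test_site_totals_conserved_and_match_enumeration(self, rng):
        """300 random sense codons: N + S = 900 and totals match an
        exhaustive 9-change enumeration done independently here."""
        from Bio.Data import CodonTable

        sense = sorted(CodonTable.unambiguous_dna_by_id[11].forward_table)
        codons = [sense[i] for i in rng.integers(0, len(sense), 300)]
        gene = "".join(codons)
        m = SnpMatrix.from_alleles([], [], {"g1": "", "g2": ""})
        eff = coding_effects(m, [("gene1", 0, 900, "+")], gene)
        assert eff.n_sites + eff.s_sites == pytest.approx(900.0)
        s_expected = 0.0
        for codon in codons:
            aa = str(Seq(codon).translate(table=11))
            syn = sum(
                1
                for i in range(3)
                for b in "ACGT"
                if b != codon[i]
                and str(Seq(codon[:i] + b + codon[i + 1 :]).translate(table=11)) == aa
            )
            s_expected += syn / 3
        assert eff.s_sites == pytest.approx(s_expected)

    def test_snp_effects_classified(self):
        # gene 'ATG AAA TAT' (+): M K Y; change AAA->AAG syn at pos 5,
        # TAT->GAT nonsyn at pos 6, AAA->TAA creates a stop (nonsense) at pos 3
        gene = "ATGAAATAT"
        ref = gene + "C" * 21
        m = SnpMatrix.from_alleles(
            [5, 6, 3],
            [ref[5], ref[6], ref[3]],
            {"g1": "G" + "G" + "T", "g2": ref[5] + ref[6] + ref[3]},
        )
        eff = coding_effects(m, [("g", 0, 9, "+")], ref)
        by_pos = {e.position: e.effect for e in eff.effects}
        assert by_pos[5] == "synonymous"
        assert by_pos[6] == "nonsynonymous"
        assert by_pos[3] == "nonsense"

    def test_reverse_strand_gene(self):
        from clonalpop._kmer import revcomp

        coding = "ATGAAATAT"
        ref = revcomp(coding) + "A" * 21
        # coding-strand synonymous change AAA->AAG is ref position 3 on '-'
        m = SnpMatrix.from_alleles([3], [ref[3]], {"g1": "C", "g2": ref[3]})
        eff = coding_effects(m, [("g", 0, 9, "-")], ref)
        assert eff.effects[0].effect == "synonymous"

    def test_internal_stop_rejected(self):
        ref = "ATGTAAAAA" + "C" * 21
        m = SnpMatrix.from_alleles([], [], {"g1": "", "g2": ""})
        with pytest.raises(ValueError, match="stop"):
            coding_effects(m, [("g", 0, 9, "+")], ref)

    def test_length_not_multiple_of_three_rejected(self):
        m = SnpMatrix.from_alleles([], [], {"g1": "", "g2": ""})
        with pytest.raises(ValueError, match="divisible"):
            coding_effects(m, [("g", 0, 8, "+")], "ATGAAATA" + "C" * 10)


class TestDnds:
    def test_study_scale_ratio(self):
        assert dnds(53, 41, 1.3e6, 3.6e5) == pytest.approx(0.358, abs=0.001)

    def test_symmetric_inputs_give_one(self):
        assert dnds(10, 10, 100, 100) == pytest.approx(1.0)

    def test_zero_nonsynonymous(self):
        assert dnds(0, 5, 100, 100) == 0.0

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            dnds(5, 0, 100, 100)
        with pytest.raises(ValueError):
            dnds(5, 5, 0, 100)


class TestMultiHitGenes:
    def _effects(self, ref, genes, rows, positions, ref_alleles):
        m = SnpMatrix.from_alleles(positions, ref_alleles, rows)
        return m, coding_effects(m, genes, ref)

    def test_no_multi_hit_empty(self):
        ref = "ATGAAATAT" + "C" * 21
        m, eff = self._effects(ref, [("g", 0, 9, "+")], {"g1": "G", "g2": "A"}, [5], [ref[5]])
        cl = classify_alleles(m, {"g1": "A", "g2": "A"})
        report = multi_hit_genes(eff, cl, genes=[("g", 0, 9, "+")])
        assert report.empty

    def test_fixed_partition_row_shape(self):
        # three nonsynonymous SNPs fixed vs reference in one gene -> (0, 3, 0)
        coding = "ATGAAATATCCC"
        ref = coding + "G" * 18
        positions = [3, 6, 9]
        ref_alleles = [ref[p] for p in positions]
        rows = {"g1": "CGA", "g2": "CGA"}  # both genomes carry all three
        m, eff = self._effects(ref, [("g", 0, 12, "+")], rows, positions, ref_alleles)
        cl = classify_alleles(m, {"g1": "A", "g2": "B"})
        report = multi_hit_genes(eff, cl, genes=[("g", 0, 12, "+")])
        row = report[report.partition == "fixed_vs_reference"].iloc[0]
        assert row.nonsyn >= 2 and row.syn + row.nonsyn == 3 and row.indel == 0

    def test_variable_partition_with_indels(self, small_population, small_core):
        cfg, _, truth = small_population
        from clonalpop.popstats import classify_alleles

        genes = [(g.gene_id, g.start, g.end, g.strand) for g in truth.genes]
        eff = coding_effects(
            small_core.matrix, genes, truth.reference, small_core.unique_non_snp_variants()
        )
        cl = classify_alleles(small_core.matrix, truth.clades)
        report = multi_hit_genes(
            eff, cl, indels=small_core.unique_non_snp_variants(), genes=genes
        )
        for _, row in report.iterrows():
            assert row.syn + row.nonsyn + row.indel >= 2
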