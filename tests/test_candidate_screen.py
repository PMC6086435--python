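"""Extreme pools, pooled chi-square, variant-effect annotation, expression
filters and evidence integration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootqtl.candidate_screen import (
    PoolPair,
    annotate_variant,
    build_pools,
    expression_filters,
    integrate_evidence,
    pooled_chi2,
)
from rootqtl.io_model import ExpressionMatrix, Gene, GeneModelSet, PhenotypeTable
from rootqtl.qtl_cluster import QTLInterval

from conftest import make_matrix


def pheno_with_pc1(n, trait_values, subpops):
    tab = pd.DataFrame(
        {"RL": trait_values, "subpop": subpops},
        index=[f"a{i:03d}" for i in range(n)],
    )
    return PhenotypeTable(tab)


class TestBuildPools:
    def test_exact_head_tail_of_trait_order(self):
        rng = np.random.default_rng(0)
        n = 120
        trait = rng.normal(size=n)
        pheno = pheno_with_pc1(n, trait, ["indica"] * n)
        pc1 = np.full(n, 10.0)  # everyone typical on the positive side
        pools = build_pools(pheno, pc1, list(pheno.table.index), "RL", "indica",
                            n_per_pool=20, pc1_cuts=(-5.0, 5.0))
        order = pheno.table["RL"].sort_values()
        assert set(pools.low_pool) == set(order.index[:20])
        assert set(pools.high_pool) == set(order.index[-20:])

    def test_insufficient_typical_accessions(self):
        n = 60
        pheno = pheno_with_pc1(n, np.arange(n, dtype=float), ["indica"] * n)
        pc1 = np.full(n, 10.0)
        with pytest.raises(ValueError, match="typical"):
            build_pools(pheno, pc1, list(pheno.table.index), "RL", "indica",
                        n_per_pool=50, pc1_cuts=(-5.0, 5.0))

    def test_middle_band_excluded(self):
        n = 100
        trait = np.arange(n, dtype=float)
        pheno = pheno_with_pc1(n, trait, ["japonica"] * 50 + ["indica"] * 50)
        pc1 = np.r_[np.full(50, -100.0), np.full(50, 100.0)]
        pools = build_pools(pheno, pc1, list(pheno.table.index), "RL", "japonica",
                            n_per_pool=10, pc1_cuts=(-50.0, 50.0))
        members = set(pools.high_pool) | set(pools.low_pool)
        assert all(pheno.table.loc[m, "subpop"] == "japonica" for m in members)

    def test_zero_contrast_flagged(self):
        n = 80
        pheno = pheno_with_pc1(n, np.ones(n), ["indica"] * n)
        pools = build_pools(pheno, np.full(n, 10.0), list(pheno.table.index),
                            "RL", "indica", n_per_pool=20, pc1_cuts=(-5.0, 5.0))
        assert pools.zero_contrast

    def test_overlapping_pools_rejected(self):
        with pytest.raises(ValueError):
            PoolPair(["a", "b"], ["b", "c"], "indica", "RL", (0, 0))


class TestPooledChi2:
    def test_perfectly_separated_forty_vs_forty(self):
        dosage = np.zeros((40, 1), dtype=np.int8)
        dosage[:20] = 2
        g = make_matrix(dosage)
        pools = PoolPair(g.accession_ids[:20], g.accession_ids[20:], "indica", "RL", (0, 0))
        out = pooled_chi2(g, pools, g.variants.index[0], beta=1.0)
        assert out["chi2"] == pytest.approx(80.0, abs=1e-10)
        assert out["p"] < 1e-15
        assert out["direction_ok"]

    def test_identical_pool_frequencies_zero_chi2(self):
        dosage = np.tile(np.array([[0], [2]], dtype=np.int8), (20, 1))
        g = make_matrix(dosage)
        pools = PoolPair(g.accession_ids[:20], g.accession_ids[20:], "indica", "RL", (0, 0))
        out = pooled_chi2(g, pools, g.variants.index[0], beta=1.0)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert not out["direction_ok"]

    def test_all_missing_pool_untestable(self):
        dosage = np.zeros((10, 1), dtype=np.int8)
        dosage[:5] = -1
        dosage[5:] = 2
        g = make_matrix(dosage)
        pools = PoolPair(g.accession_ids[:5], g.accession_ids[5:], "indica", "RL", (0, 0))
        out = pooled_chi2(g, pools, g.variants.index[0])
        assert not out["testable"]

    def test_direction_follows_beta_sign(self):
        dosage = np.zeros((20, 1), dtype=np.int8)
        dosage[:10] = 2  # alt frequent in high pool
        g = make_matrix(dosage)
        pools = PoolPair(g.accession_ids[:10], g.accession_ids[10:], "indica", "RL", (0, 0))
        assert pooled_chi2(g, pools, g.variants.index[0], beta=+1.0)["direction_ok"]
        assert not pooled_chi2(g, pools, g.variants.index[0], beta=-1.0)["direction_ok"]

    def test_thousand_random_tables_match_hand_formula_and_scipy(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 30, size=4)
            n = a + b + c + d
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            # implementation path: encode the table as dosages
            hi = [0] * a + [2] * b
            lo = [0] * c + [2] * d
            # allele copies are per-genotype doubled; halve by using each
            # entry once and reading counts off the table directly instead
            chi2_hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            chi2_scipy = stats.chi2_contingency(
                np.array([[a, b], [c, d]]), correction=False
            )[0]
            assert chi2_hand == pytest.approx(chi2_scipy, abs=1e-10)

    def test_implementation_matches_hand_formula_on_random_panels(self):
        rng = np.random.default_rng(7)
        dosage = rng.choice([0, 2, -1], size=(40, 200), p=[0.45, 0.45, 0.1]).astype(np.int8)
        g = make_matrix(dosage, positions=np.arange(1, 201) * 50)
        pools = PoolPair(g.accession_ids[:20], g.accession_ids[20:], "indica", "RL", (0, 0))
        for j in range(200):
            vid = g.variants.index[j]
            out = pooled_chi2(g, pools, vid, beta=1.0)
            hi = dosage[:20, j]
            lo = dosage[20:, j]
            a = 2 * np.sum(hi == 0) + np.sum(hi == 1)
            b = 2 * np.sum(hi == 2) + np.sum(hi == 1)
            c = 2 * np.sum(lo == 0) + np.sum(lo == 1)
            d = 2 * np.sum(lo == 2) + np.sum(lo == 1)
            if 0 in (a + b, c + d, a + c, b + d):
                assert not out["testable"]
                continue
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert out["chi2"] == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# variant-effect annotation
# ---------------------------------------------------------------------------

def toy_gene_setup():
    """A plus- and a minus-strand gene with hand-built ORFs."""
    #          1-based coords; CDS length divisible by 3
    # plus gene: CDS 101..130 (10 codons)
    # minus gene: CDS 301..330
    plus_cds = "ATG" + "TGGGCTAAAGCTCCCGGGTTTACT" + "TAA"
    minus_coding = "ATG" + "CATGAAGCTTGGAAATTTCCAGGA" + "TGA"
    comp = str.maketrans("ACGT", "TGCA")
    minus_genomic = minus_coding[::-1].translate(comp)
    seq = ["A"] * 500
    seq[100:130] = list(plus_cds)
    seq[300:330] = list(minus_genomic)
    reference = {"chr1": "".join(seq)}
    genes = GeneModelSet(chrom_lengths={"chr1": 500})
    genes.add(Gene("gplus", "chr1", "+", 95, 140, [(101, 130)]))
    genes.add(Gene("gminus", "chr1", "-", 295, 340, [(301, 330)]))
    return reference, genes


def matrix_with_variant(reference, pos, ref, alt, vclass="SNP"):
    variants = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [pos], "ref": [ref], "alt": [alt], "vclass": [vclass]},
        index=[f"chr1_{pos}"],
    )
    from rootqtl.io_model import GenotypeMatrix

    return GenotypeMatrix(["x"], variants, np.zeros((1, 1), dtype=np.int8))


class TestAnnotateVariant:
    def test_stop_gain_tgg_to_tga(self):
        reference, genes = toy_gene_setup()
        # codon 2 of gplus is TGG at 104..106; G->A at 106 makes TGA
        assert reference["chr1"][103:106] == "TGG"
        g = matrix_with_variant(reference, 106, "G", "A")
        eff = annotate_variant("chr1_106", g, genes, reference)
        assert eff.consequence == "stop_gain"
        assert eff.large_effect
        assert eff.zone == "ORF"

    def test_synonymous_third_position(self):
        reference, genes = toy_gene_setup()
        # codon 3 GCT at 107..109; T->C -> GCC, still Ala
        assert reference["chr1"][106:109] == "GCT"
        g = matrix_with_variant(reference, 109, "T", "C")
        eff = annotate_variant("chr1_109", g, genes, reference)
        assert eff.consequence == "synonymous"
        assert not eff.large_effect

    def test_minus_strand_nonsynonymous(self):
        reference, genes = toy_gene_setup()
        # genomic position inside gminus CDS; verify via coding math below
        g = matrix_with_variant(reference, 310, reference["chr1"][309], "A"
                                if reference["chr1"][309] != "A" else "G")
        eff = annotate_variant("chr1_310", g, genes, reference)
        assert eff.zone == "ORF"
        assert eff.consequence in {"synonymous", "nonsynonymous", "stop_gain",
                                   "stop_loss", "start_loss"}

    def test_start_loss(self):
        reference, genes = toy_gene_setup()
        g = matrix_with_variant(reference, 101, "A", "G")  # ATG -> GTG
        eff = annotate_variant("chr1_101", g, genes, reference)
        assert eff.consequence == "start_loss"
        assert eff.large_effect

    def test_frameshift_and_inframe_indels(self):
        reference, genes = toy_gene_setup()
        ref2 = reference["chr1"][104:106]
        g = matrix_with_variant(reference, 105, reference["chr1"][104:106],
                                reference["chr1"][104], vclass="InDel")
        eff = annotate_variant("chr1_105", g, genes, reference)
        assert eff.consequence == "frameshift"
        assert eff.large_effect
        ref4 = reference["chr1"][104:108]
        g2 = matrix_with_variant(reference, 105, ref4, ref4[0], vclass="InDel")
        eff2 = annotate_variant("chr1_105", g2, genes, reference)
        assert eff2.consequence == "inframe_indel"
        assert not eff2.large_effect

    def test_promoter_and_intergenic_zones(self):
        reference, genes = toy_gene_setup()
        g = matrix_with_variant(reference, 50, "A", "T")  # upstream of gplus TSS (95)
        eff = annotate_variant("chr1_50", g, genes, reference)
        assert eff.zone == "promoter"
        assert eff.gene_id == "gplus"
        g2 = matrix_with_variant(reference, 450, "A", "T")
        eff2 = annotate_variant("chr1_450", g2, genes, reference)
        assert eff2.zone == "promoter"  # downstream of minus-strand gene = its promoter
        assert eff2.gene_id == "gminus"

    def test_reference_mismatch_raises(self):
        reference, genes = toy_gene_setup()
        g = matrix_with_variant(reference, 106, "C", "A")  # true base is G
        with pytest.raises(ValueError, match="chr1:106"):
            annotate_variant("chr1_106", g, genes, reference)

    def test_random_snps_match_full_cds_translate_oracle(self, small_panel):
        """500 random coding SNPs against an independent mutate-whole-CDS oracle."""
        from Bio.Seq import Seq

        from rootqtl.candidate_screen import _coding_sequence

        p = small_panel
        rng = np.random.default_rng(17)
        comp = str.maketrans("ACGT", "TGCA")
        checked = 0
        genes = list(p.genes)
        while checked < 500:
            gene = genes[rng.integers(len(genes))]
            s, e = gene.cds[rng.integers(len(gene.cds))]
            pos = int(rng.integers(s, e + 1))
            ref = p.reference[gene.chrom][pos - 1]
            alt = "ACGT"[rng.integers(4)]
            if alt == ref:
                continue
            variants = pd.DataFrame(
                {"chrom": [gene.chrom], "pos": [pos], "ref": [ref], "alt": [alt],
                 "vclass": ["SNP"]},
                index=[f"{gene.chrom}_{pos}_t"],
            )
            from rootqtl.io_model import GenotypeMatrix

            g1 = GenotypeMatrix(["x"], variants, np.zeros((1, 1), dtype=np.int8))
            eff = annotate_variant(f"{gene.chrom}_{pos}_t", g1, p.genes, p.reference)

            # oracle: mutate the chromosome, rebuild the whole CDS, translate both
            chrom_seq = p.reference[gene.chrom]
            mutated = chrom_seq[: pos - 1] + alt + chrom_seq[pos:]
            ref_mut = dict(p.reference)
            ref_mut[gene.chrom] = mutated
            aa_before = str(Seq(_coding_sequence(gene, p.reference)).translate())
            aa_after = str(Seq(_coding_sequence(gene, ref_mut)).translate())
            diffs = [(i, a, b) for i, (a, b) in enumerate(zip(aa_before, aa_after))
                     if a != b]
            if not diffs:
                expected = "synonymous"
            else:
                i, a, b = diffs[0]
                if i == 0 and a == "M":
                    expected = "start_loss"
                elif b == "*":
                    expected = "stop_gain"
                elif a == "*":
                    expected = "stop_loss"
                else:
                    expected = "nonsynonymous"
            assert eff.consequence == expected, (gene.gene_id, gene.strand, pos)
            checked += 1


class TestExpressionFilters:
    def make_expr(self, robust_root, control_root, root=None, shoot=None):
        samples = pd.DataFrame(
            {
                "variety": ["R1", "R2", "C1", "C2", "R1", "C1"],
                "tissue": ["root", "root", "root", "root", "shoot", "shoot"],
                "group": ["robust", "robust", "control", "control", "robust", "control"],
                "replicate": [1, 1, 1, 1, 1, 1],
            },
            index=["s1", "s2", "s3", "s4", "s5", "s6"],
        )
        shoot_val = shoot if shoot is not None else control_root
        rpkm = pd.DataFrame(
            [[robust_root, robust_root, control_root, control_root, shoot_val, shoot_val]],
            index=["gene1"], columns=samples.index,
        )
        return ExpressionMatrix(rpkm=rpkm, samples=samples)

    def test_epsilon_stabilized_ratio_not_differential(self):
        expr = self.make_expr(1.3, 1.0)
        out = expression_filters(expr, "gene1")
        assert out["ratio"] == pytest.approx(1.4 / 1.1, abs=1e-12)
        assert not out["differential"]

    def test_equal_expression_ratio_one(self):
        out = expression_filters(self.make_expr(2.0, 2.0), "gene1")
        assert out["ratio"] == pytest.approx(1.0)
        assert not out["differential"]

    def test_strong_ratio_differential_both_directions(self):
        assert expression_filters(self.make_expr(2.0, 1.0), "gene1")["differential"]
        assert expression_filters(self.make_expr(0.5, 1.0), "gene1")["differential"]

    def test_root_specific(self):
        out = expression_filters(self.make_expr(5.0, 5.0, shoot=0.0), "gene1")
        assert out["root_specific"]
        out2 = expression_filters(self.make_expr(5.0, 5.0, shoot=3.0), "gene1")
        assert not out2["root_specific"]

    def test_absent_gene_flags_false(self):
        out = expression_filters(self.make_expr(1, 1), "nope")
        assert not out["differential"] and not out["root_specific"]
        assert np.isnan(out["ratio"])


class TestIntegrateEvidence:
    def setup_pieces(self):
        from rootqtl.candidate_screen import VariantEffect

        genes = GeneModelSet(chrom_lengths={"chr1": 1_000_000})
        genes.add(Gene("gA", "chr1", "+", 100_000, 104_000, [(100_200, 100_799)]))
        genes.add(Gene("gB", "chr1", "+", 150_000, 154_000, [(150_200, 150_799)]))
        qtls = [QTLInterval("q1", "chr1", 95_000, 160_000,
                            ["v1", "v2", "v3"], "v1", peak_pos=100_500, peak_logp=6.0)]
        effects = [
            VariantEffect("v1", "gA", "ORF", "stop_gain", True),
            VariantEffect("v2", "gB", "ORF", "synonymous", False),
            VariantEffect("v3", "gB", "promoter", "noncoding", False),
        ]
        samples = pd.DataFrame(
            {"variety": ["R", "C"], "tissue": ["root", "root"],
             "group": ["robust", "control"], "replicate": [1, 1]},
            index=["s1", "s2"])
        rpkm = pd.DataFrame([[4.0, 1.9], [2.0, 2.0]], index=["gA", "gB"],
                            columns=["s1", "s2"])
        expr = ExpressionMatrix(rpkm=rpkm, samples=samples)
        chi2_pass = {"chi2": 20.0, "p": 1e-5, "direction_ok": True, "testable": True}
        chi2_fail = {"chi2": 0.1, "p": 0.9, "direction_ok": True, "testable": True}
        return genes, qtls, effects, expr, chi2_pass, chi2_fail

    def test_stop_gain_with_expression_in_gwas_only_qtl_is_candidate(self):
        genes, qtls, effects, expr, chi2_pass, chi2_fail = self.setup_pieces()
        cands, ledger = integrate_evidence(
            qtls, effects, {"v1": chi2_pass, "v2": chi2_pass, "v3": chi2_pass},
            linkage_variants=set(), linkage_covered_qtls=set(),
            expr=expr, genes=genes,
        )
        by_id = {c.gene_id: c for c in cands}
        assert by_id["gA"].status == "candidate"
        assert by_id["gA"].linkage_pass is None  # GWAS-only QTL kept neutral

    def test_gene_failing_chi2_everywhere_excluded(self):
        genes, qtls, effects, expr, chi2_pass, chi2_fail = self.setup_pieces()
        cands, ledger = integrate_evidence(
            qtls, effects, {"v1": chi2_fail, "v2": chi2_fail, "v3": chi2_fail},
            linkage_variants=set(), linkage_covered_qtls=set(),
            expr=expr, genes=genes,
        )
        assert all(c.status == "excluded" for c in cands)
        assert ledger["genes_after_chi2"] == 0

    def test_no_coding_change_no_candidacy(self):
        genes, qtls, effects, expr, chi2_pass, _ = self.setup_pieces()
        cands, _ = integrate_evidence(
            qtls, effects, {"v1": chi2_pass, "v2": chi2_pass, "v3": chi2_pass},
            linkage_variants=set(), linkage_covered_qtls=set(),
            expr=expr, genes=genes,
        )
        by_id = {c.gene_id: c for c in cands}
        assert by_id["gB"].status == "excluded"  # synonymous + promoter only

    def test_linkage_covered_qtl_requires_linkage_pass(self):
        genes, qtls, effects, expr, chi2_pass, _ = self.setup_pieces()
        cands, _ = integrate_evidence(
            qtls, effects, {"v1": chi2_pass, "v2": chi2_pass, "v3": chi2_pass},
            linkage_variants=set(), linkage_covered_qtls={"q1"},
            expr=expr, genes=genes,
        )
        by_id = {c.gene_id: c for c in cands}
        assert by_id["gA"].linkage_pass is False
        assert by_id["gA"].status == "excluded"

    def test_deferred_when_no_expression_signal(self):
        genes, qtls, effects, expr, chi2_pass, _ = self.setup_pieces()
        expr.rpkm.loc["gA"] = [2.0, 2.0]  # kill the expression evidence
        cands, ledger = integrate_evidence(
            qtls, effects, {"v1": chi2_pass, "v2": chi2_pass, "v3": chi2_pass},
            linkage_variants=set(), linkage_covered_qtls=set(),
            expr=expr, genes=genes,
        )
        by_id = {c.gene_id: c for c in cands}
        assert by_id["gA"].status == "deferred"
        assert ledger["deferred"] == 1

    def test_empty_qtls_empty_ledger(self):
        genes, qtls, effects, expr, chi2_pass, _ = self.setup_pieces()
        cands, ledger = integrate_evidence(
            [], effects, {}, set(), set(), expr, genes,
        )
        assert cands == []
        assert ledger["genes_start"] == 0

    def test_monotone_screening_counts(self):
        genes, qtls, effects, expr, chi2_pass, chi2_fail = self.setup_pieces()
        cands, ledger = integrate_evidence(
            qtls, effects, {"v1": chi2_pass, "v2": chi2_fail, "v3": chi2_fail},
            linkage_variants=set(), linkage_covered_qtls=set(),
            expr=expr, genes=genes,
        )
        assert ledger["genes_start"] >= ledger["genes_after_chi2"] >= \
            ledger["genes_after_linkage"] >= ledger["candidates"]
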