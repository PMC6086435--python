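"""Four-step candidate-gene shortlisting inside called QTLs.

Steps, mirrored as evidence flags accumulated per gene:

1. Extreme-pool allele-frequency screen: two pools of phenotypically extreme
   accessions drawn from the PC1-typical region of a subpopulation; per-SNP
   Pearson chi-square on the 2x2 allele-copy table, direction-checked
   against the GWAS effect sign.
2. Linkage-mapping filter: significant SNPs must fall in GWAS-by-linkage
   interval overlaps with differing parental genotypes (via
   :mod:`rootqtl.qtl_cluster`); QTLs with no linkage coverage keep a
   neutral flag so GWAS-only QTLs are retained.
3. Variant-effect annotation: ORF SNPs are classified by codon translation
   (strand-aware); large-effect = stop gain/loss, start loss, frameshift,
   or a splice-boundary hit within 2 bp of an internal CDS junction.
4. Expression-pattern filters on the robust/control root RPKM ratio
   (> 1.3 or < 0.77, with a pseudo-count) and root-specific expression.

A gene with coding evidence but no expression signal is *deferred*: it is
resolved by the haplotype-phenotype test
(:func:`rootqtl.haplotype_stats.finalize_deferred_candidates`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    ExpressionMatrix,
    Gene,
    GeneModelSet,
    GenotypeMatrix,
    MISSING,
    PhenotypeTable,
    logger,
)

RPKM_EPSILON = 0.1
RATIO_HIGH = 1.3
RATIO_LOW = 0.77
LARGE_EFFECT = {"stop_gain", "stop_loss", "start_loss", "frameshift", "splice_boundary"}


# ---------------------------------------------------------------------------
# extreme pools
# ---------------------------------------------------------------------------

@dataclass
class PoolPair:
    high_pool: list
    low_pool: list
    subpop: str
    trait: str
    pc1_cuts: tuple
    zero_contrast: bool = False

    def __post_init__(self) -> None:
        if set(self.high_pool) & set(self.low_pool):
            raise ValueError("extreme pools overlap")


def build_pools(
    pheno: PhenotypeTable,
    pc1: np.ndarray,
    pc1_accessions: list,
    trait: str,
    subpop: str,
    n_per_pool: int = 20,
    pc1_cuts: tuple | None = None,
    subpop_column: str = "subpop",
) -> PoolPair:
    """High/low trait pools within the PC1-typical region of ``subpop``.

    ``pc1_cuts=(low, high)``: accessions with PC1 < low are typical members
    of the subpopulation on the negative side, PC1 > high on the positive
    side; the band in between is excluded as admixed. When ``pc1_cuts`` is
    None the middle 20% of PC1 is excluded (quantile rule). Which side is
    "typical" for the requested subpopulation is decided by the sign of the
    mean PC1 of accessions labelled with it. Ties on the trait are broken
    by accession id.
    """
    s = pd.Series(pc1, index=pc1_accessions)
    s = s[s.index.isin(pheno.table.index)]
    traits = pheno.table.loc[s.index, trait]
    ok = traits.notna()
    s, traits = s[ok], traits[ok]
    if pc1_cuts is None:
        pc1_cuts = (float(s.quantile(0.40)), float(s.quantile(0.60)))
    lo_cut, hi_cut = pc1_cuts

    labels = pheno.table.loc[s.index, subpop_column]
    side_mean = s[labels == subpop].mean()
    if np.isnan(side_mean):
        raise ValueError(f"no accessions labelled {subpop!r}")
    typical = s > hi_cut if side_mean >= s.mean() else s < lo_cut
    members = traits[typical]
    if len(members) < 2 * n_per_pool:
        raise ValueError(
            f"{len(members)} typical {subpop} accessions < 2 x n_per_pool ({2 * n_per_pool})"
        )
    ranked = members.loc[sorted(members.index)].sort_values(kind="mergesort")  # id-order ties
    low = list(ranked.index[:n_per_pool])
    high = list(ranked.index[-n_per_pool:])
    zero_contrast = bool(ranked.iloc[-1] == ranked.iloc[0])
    if zero_contrast:
        logger.warning("build_pools: zero trait contrast between pools (%s/%s)", subpop, trait)
    return PoolPair(
        high_pool=high, low_pool=low, subpop=subpop, trait=trait,
        pc1_cuts=pc1_cuts, zero_contrast=zero_contrast,
    )


def pooled_chi2(g: GenotypeMatrix, pools: PoolPair, variant_id: str,
                beta: float | None = None) -> dict:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    allele-copy table ref/alt x high/low pool.

    ``direction_ok`` is True when the trait-increasing allele (alt if the
    GWAS beta is positive, ref if negative) is more frequent in the high
    pool. Returns dict with chi2, p, direction_ok, testable.
    """
    from scipy import stats

    vcol = g.variants.index.get_loc(variant_id)
    counts = {}
    for name, pool in (("high", pools.high_pool), ("low", pools.low_pool)):
        d = g.dosage[g.accession_index(pool), vcol]
        called = d != MISSING
        alt = int(d[called].sum())
        ref = int(2 * called.sum() - alt)
        counts[name] = (ref, alt)
    a, b = counts["high"]  # ref, alt in high pool
    c, d_ = counts["low"]
    n = a + b + c + d_
    row1, row2, col1, col2 = a + b, c + d_, a + c, b + d_
    if 0 in (row1, row2, col1, col2):
        return {"chi2": np.nan, "p": np.nan, "direction_ok": False, "testable": False}
    chi2 = n * (a * d_ - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1))
    alt_high = b / row1
    alt_low = d_ / row2
    if beta is None or beta >= 0:
        direction_ok = alt_high > alt_low
    else:
        direction_ok = alt_high < alt_low
    return {"chi2": float(chi2), "p": p, "direction_ok": bool(direction_ok), "testable": True}


# ---------------------------------------------------------------------------
# variant-effect annotation
# ---------------------------------------------------------------------------

@dataclass
class VariantEffect:
    variant_id: str
    gene_id: str | None
    zone: str            # ORF / promoter / intergenic
    consequence: str     # synonymous/nonsynonymous/stop_gain/stop_loss/start_loss/
                         # frameshift/inframe_indel/splice_boundary/noncoding
    large_effect: bool
    aa_change: str | None = None

    @property
    def is_defining(self) -> bool:
        """Usable for gene haplotypes: non-synonymous/large-effect ORF or promoter."""
        if self.zone == "promoter":
            return True
        return self.consequence in {"nonsynonymous"} | LARGE_EFFECT


_CODE = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s[::-1].translate(_CODE)


def _coding_sequence(gene: Gene, reference: dict) -> str:
    seq = reference[gene.chrom]
    genomic = "".join(seq[s - 1 : e] for s, e in gene.cds)
    return genomic if gene.strand == "+" else _revcomp(genomic)


def _coding_index(gene: Gene, pos: int) -> int | None:
    """0-based index of genomic position ``pos`` in the coding sequence."""
    offset = 0
    total = gene.cds_length()
    for s, e in gene.cds:
        if s <= pos <= e:
            idx = offset + (pos - s)
            return idx if gene.strand == "+" else total - 1 - idx
        offset += e - s + 1
    return None


def _splice_window(gene: Gene, pos: int) -> bool:
    """Within 2 bp of an internal CDS junction, on the intron side."""
    if len(gene.cds) < 2:
        return False
    for i, (s, e) in enumerate(gene.cds):
        if i > 0 and s - 2 <= pos <= s - 1:
            return True
        if i < len(gene.cds) - 1 and e + 1 <= pos <= e + 2:
            return True
    return False


def annotate_variant(variant_id: str, g: GenotypeMatrix, genes: GeneModelSet,
                     reference: dict) -> VariantEffect:
    """Assign zone and coding consequence to one variant.

    The reference base(s) at the position must match the VCF REF allele.
    CDS SNPs are translated codon-wise with the standard genetic code,
    reverse-complemented on minus-strand genes.
    """
    from Bio.Seq import Seq

    row = g.variants.loc[variant_id]
    chrom, pos, ref, alt = row["chrom"], int(row["pos"]), row["ref"], row["alt"]
    seq = reference[chrom]
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref!r}, "
            f"found {seq[pos - 1 : pos - 1 + len(ref)]!r}"
        )

    chrom_len = genes.chrom_lengths.get(chrom, len(seq))
    hit_gene, zone = None, "intergenic"
    for gene in genes.genes_on(chrom):
        if any(s <= pos <= e for s, e in gene.cds):
            hit_gene, zone = gene, "ORF"
            break
        plo, phi = gene.promoter(chrom_len)
        if plo <= pos <= phi:
            hit_gene, zone = gene, "promoter"
        elif _splice_window(gene, pos):
            return VariantEffect(variant_id, gene.gene_id, "intergenic",
                                 "splice_boundary", True)

    if zone != "ORF":
        return VariantEffect(
            variant_id, hit_gene.gene_id if hit_gene else None, zone, "noncoding", False
        )

    gene = hit_gene
    if len(ref) != len(alt):  # InDel in CDS
        shift = abs(len(ref) - len(alt)) % 3
        cons = "frameshift" if shift != 0 else "inframe_indel"
        return VariantEffect(variant_id, gene.gene_id, zone, cons, cons == "frameshift")

    cds = _coding_sequence(gene, reference)
    idx = _coding_index(gene, pos)
    codon_i = idx // 3
    within = idx % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    new_base = alt if gene.strand == "+" else alt.translate(_CODE)
    new_codon = codon[:within] + new_base + codon[within + 1 :]
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(new_codon).translate())
    if codon_i == 0 and aa_old == "M" and aa_new != "M":
        cons = "start_loss"
    elif aa_old != "*" and aa_new == "*":
        cons = "stop_gain"
    elif aa_old == "*" and aa_new != "*":
        cons = "stop_loss"
    elif aa_old == aa_new:
        cons = "synonymous"
    else:
        cons = "nonsynonymous"
    return VariantEffect(
        variant_id, gene.gene_id, zone, cons, cons in LARGE_EFFECT,
        aa_change=f"{aa_old}{codon_i + 1}{aa_new}",
    )


# ---------------------------------------------------------------------------
# expression filters
# ---------------------------------------------------------------------------

def expression_filters(expr: ExpressionMatrix, gene_id: str) -> dict:
    """Robust/control root RPKM ratio and the two expression flags.

    ratio = (mean robust-root RPKM + eps) / (mean control-root RPKM + eps),
    eps = 0.1. differential iff ratio > 1.3 or < 0.77. root_specific iff
    mean root RPKM >= 1 and mean shoot RPKM < 1.
    """
    if gene_id not in expr.rpkm.index:
        logger.warning("expression_filters: gene %s absent from RPKM matrix", gene_id)
        return {"ratio": np.nan, "differential": False, "root_specific": False}
    row = expr.rpkm.loc[gene_id]
    robust_root = row[expr.sample_ids(tissue="root", group="robust")].mean()
    control_root = row[expr.sample_ids(tissue="root", group="control")].mean()
    ratio = (robust_root + RPKM_EPSILON) / (control_root + RPKM_EPSILON)
    differential = bool(ratio > RATIO_HIGH or ratio < RATIO_LOW)
    mean_root = row[expr.sample_ids(tissue="root")].mean()
    mean_shoot = row[expr.sample_ids(tissue="shoot")].mean()
    root_specific = bool(mean_root >= 1.0 and mean_shoot < 1.0)
    return {"ratio": float(ratio), "differential": differential, "root_specific": root_specific}


# ---------------------------------------------------------------------------
# evidence integration
# ---------------------------------------------------------------------------

@dataclass
class CandidateGene:
    gene_id: str
    qtl_id: str
    variant_ids: list
    pool_chi2_pass: bool
    linkage_pass: bool | None          # None = QTL has no linkage coverage (neutral)
    has_nonsyn_or_large_effect: bool
    expression_differential: bool
    root_specific: bool
    rpkm_ratio: float
    best_chi2_p: float
    status: str = "excluded"           # excluded / candidate / deferred

    def linkage_ok(self) -> bool:
        return self.linkage_pass is None or self.linkage_pass


def integrate_evidence(
    qtls: list,
    effects: list,
    chi2_results: dict,
    linkage_variants: set,
    linkage_covered_qtls: set,
    expr: ExpressionMatrix,
    genes: GeneModelSet,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> tuple:
    """Combine the four evidence streams into per-gene candidate calls.

    ``effects``: VariantEffect for every significant variant in the QTLs.
    ``chi2_results``: variant id -> dict from :func:`pooled_chi2` (any one
    pool pair; callers may pre-merge several by best p).
    Returns (list of CandidateGene, stage-count ledger dict). Screening is
    monotone: each stage only removes genes.
    """
    by_gene: dict = {}
    gene_qtl: dict = {}
    for eff in effects:
        if eff.gene_id is None or eff.zone == "intergenic":
            continue
        by_gene.setdefault(eff.gene_id, []).append(eff)
    for gid, effs in by_gene.items():
        gene = genes[gid]
        for q in qtls:
            if q.chrom == gene.chrom and q.start <= gene.end and q.end >= gene.start:
                gene_qtl[gid] = q.qtl_id
                break
        else:
            # gene tagged only through promoter variants may sit just outside
            # the QTL span; attach to the QTL of its first variant if any
            for q in qtls:
                if any(v.variant_id in q.member_ids for v in effs):
                    gene_qtl[gid] = q.qtl_id
                    break

    n_tests = max(1, sum(1 for v in chi2_results.values() if v.get("testable", False)))
    alpha_eff = alpha / n_tests if bonferroni else alpha

    ledger = {
        "qtls": len(qtls),
        "genes_start": 0,
        "snps_start": 0,
        "genes_after_chi2": 0,
        "genes_after_linkage": 0,
        "candidates": 0,
        "deferred": 0,
    }
    out = []
    for gid, effs in sorted(by_gene.items()):
        if gid not in gene_qtl:
            continue
        qtl_id = gene_qtl[gid]
        vids = [e.variant_id for e in effs]
        ledger["genes_start"] += 1
        ledger["snps_start"] += len(vids)

        chi2_hits = [
            chi2_results[v] for v in vids
            if v in chi2_results and chi2_results[v].get("testable", False)
        ]
        passing = [h for h in chi2_hits if h["p"] < alpha_eff and h["direction_ok"]]
        chi2_pass = bool(passing)
        best_p = min((h["p"] for h in chi2_hits), default=np.nan)

        covered = qtl_id in linkage_covered_qtls
        linkage_pass = (any(v in linkage_variants for v in vids)) if covered else None

        nonsyn = any(
            e.zone == "ORF" and (e.consequence == "nonsynonymous" or e.large_effect)
            for e in effs
        ) or any(e.large_effect for e in effs)

        ex = expression_filters(expr, gid)

        cg = CandidateGene(
            gene_id=gid,
            qtl_id=qtl_id,
            variant_ids=vids,
            pool_chi2_pass=chi2_pass,
            linkage_pass=linkage_pass,
            has_nonsyn_or_large_effect=nonsyn,
            expression_differential=ex["differential"],
            root_specific=ex["root_specific"],
            rpkm_ratio=ex["ratio"],
            best_chi2_p=best_p,
        )
        if chi2_pass:
            ledger["genes_after_chi2"] += 1
            if cg.linkage_ok():
                ledger["genes_after_linkage"] += 1
                if nonsyn and (ex["differential"] or ex["root_specific"]):
                    cg.status = "candidate"
                    ledger["candidates"] += 1
                elif nonsyn:
                    cg.status = "deferred"
                    ledger["deferred"] += 1
        out.append(cg)
    return out, ledger


def candidates_to_frame(cands: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene_id,
                "qtl": c.qtl_id,
                "n_snps": len(c.variant_ids),
                "pool_chi2_pass": c.pool_chi2_pass,
                "linkage_pass": "" if c.linkage_pass is None else c.linkage_pass,
                "nonsyn_or_large_effect": c.has_nonsyn_or_large_effect,
                "differential": c.expression_differential,
                "root_specific": c.root_specific,
                "rpkm_ratio": c.rpkm_ratio,
                "best_chi2_p": c.best_chi2_p,
                "status": c.status,
            }
            for c in cands
        ]
    )
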