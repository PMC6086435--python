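"""End-to-end orchestration: QC -> structure -> scan -> threshold -> QTLs ->
candidate screen -> haplotype tests, on in-memory panel components.

This is glue over the analysis modules; each stage is the public function
documented in its own module. The defaults follow the published protocol
(CMLM with 3 PCs and kinship, conditional-permutation threshold at the 95th
percentile, QTLs of >= 3 significant SNPs within 170 kb, 20-accession
extreme pools, pooled chi-square at alpha = 0.05).

One deliberate departure from the published settings: the permutation
rescan covers all tested variants (prefilter = 0) rather than only those
with observed -log10(p) >= 2. At desk scale the pre-filtered set is small
enough that conditioning on the observed scan biases the threshold low;
the full rescan restores exchangeability and costs little here. Pass
``prefilter=2.0`` for the published behaviour on large panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import candidate_screen as screen
from . import haplotype_stats as hap
from . import permutation as perm
from . import qtl_cluster as qtl
from .io_model import GenotypeMatrix, qc_filter


@dataclass
class DiscoveryResult:
    genotypes: GenotypeMatrix
    structure: assoc.StructureModel
    scan: assoc.AssociationResult
    threshold: perm.ThresholdResult
    qtls: list
    pools: dict
    chi2: dict
    linkage_hits: pd.DataFrame
    candidates: list
    ledger: dict
    haplotype_results: dict


def run_discovery(
    genotypes: GenotypeMatrix,
    phenotypes,
    genes,
    reference: dict,
    expression,
    linkage_qtls,
    trait: str = "RL",
    model: str = "mlm",
    k_pcs: int = 3,
    n_perm: int = 200,
    percentile: float = 95.0,
    prefilter: float = 0.0,
    window_bp: int = 170_000,
    min_snps: int = 3,
    n_per_pool: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
    max_missing: float = 0.5,
    min_maf: float = 0.05,
) -> DiscoveryResult:
    g = qc_filter(genotypes, max_missing=max_missing, min_maf=min_maf)

    rows, y, ids = assoc._align(g, phenotypes, trait)
    structure = assoc.compute_pcs(g, k=k_pcs, rows=rows)
    structure.kinship = assoc.compute_kinship(g, rows=rows).kinship

    if model == "mlm":
        scan = assoc.scan_mlm(g, phenotypes, trait, structure)
    else:
        scan = assoc.scan_glm(g, phenotypes, trait, structure)

    thr = perm.conditional_threshold(
        g, phenotypes, trait, structure, scan, model=model,
        n_perm=n_perm, percentile=percentile, prefilter=prefilter, seed=seed,
    )
    qtls = qtl.call_qtls(scan, thr.threshold, window_bp=window_bp,
                         min_snps=min_snps, trait=trait)

    sig = scan.tested & (scan.minus_log10_p >= thr.threshold)
    sig_ids = list(g.variants.index[sig])
    beta_by_id = dict(zip(g.variants.index, scan.beta))

    # extreme pools from both typical subpopulations; per variant keep the
    # best-p passing result across pools
    pc1 = structure.pcs[:, 0]
    pools = {}
    chi2_merged: dict = {}
    for subpop in ("indica", "japonica"):
        try:
            pool = screen.build_pools(
                phenotypes, pc1, ids, trait, subpop, n_per_pool=n_per_pool
            )
        except ValueError:
            continue
        pools[subpop] = pool
        for vid in sig_ids:
            res = screen.pooled_chi2(g, pool, vid, beta=beta_by_id.get(vid))
            prev = chi2_merged.get(vid)
            if prev is None or (
                res["testable"]
                and (not prev["testable"] or (res["p"] < prev["p"] and res["direction_ok"]))
            ):
                chi2_merged[vid] = res

    linkage_hits = qtl.intersect_linkage(qtls, linkage_qtls, g, sig_ids, trait=trait)
    covered = qtl.qtls_with_linkage_coverage(qtls, linkage_qtls, trait=trait)

    effects = [screen.annotate_variant(v, g, genes, reference) for v in sig_ids]
    candidates, ledger = screen.integrate_evidence(
        qtls, effects, chi2_merged, set(linkage_hits["variant"]), covered,
        expression, genes, alpha=alpha,
    )

    # haplotype tests for genes with coding/promoter evidence
    eff_by_gene: dict = {}
    for e in effects:
        if e.gene_id is not None and e.is_defining:
            eff_by_gene.setdefault(e.gene_id, []).append(e.variant_id)
    hap_results: dict = {}
    for cg in candidates:
        defining = eff_by_gene.get(cg.gene_id, [])
        if not defining:
            continue
        try:
            table = hap.build_haplotypes(g, cg.gene_id, defining)
        except ValueError:
            continue
        results = []
        for scope in (None, "indica", "japonica"):
            try:
                results.append(hap.anova_duncan(table, phenotypes, trait, scope=scope))
            except ValueError:
                continue
        if results:
            hap_results[cg.gene_id] = results
    candidates = hap.finalize_deferred_candidates(candidates, hap_results, alpha=alpha)
    ledger["candidates_final"] = sum(1 for c in candidates if c.status == "candidate")

    return DiscoveryResult(
        genotypes=g,
        structure=structure,
        scan=scan,
        threshold=thr,
        qtls=qtls,
        pools=pools,
        chi2=chi2_merged,
        linkage_hits=linkage_hits,
        candidates=candidates,
        ledger=ledger,
        haplotype_results=hap_results,
    )
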