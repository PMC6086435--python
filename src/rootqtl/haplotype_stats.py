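"""Gene-level haplotypes and haplotype-phenotype testing.

Haplotypes are the ordered ref/alt combinations an accession carries at a
gene's defining variants (non-synonymous / large-effect ORF variants plus
promoter variants). The panel is inbred, so haplotypes are read directly
from homozygous dosages; accessions heterozygous or missing at any defining
variant are excluded and counted.

Phenotype differences among major haplotypes (frequency >= 5% by default)
are tested with one-way ANOVA; with exactly two major classes a Welch
t-test is used, with more a protected Duncan multiple-range test assigns
letter groups (haplotypes sharing a letter are not significantly different
at alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import GenotypeMatrix, MISSING, PhenotypeTable, logger


@dataclass
class HaplotypeTable:
    gene_id: str
    defining_variants: list
    assignments: pd.Series        # accession -> haplotype string like "AR" over ref(R)/alt(A)
    classes: pd.DataFrame         # index haplotype, columns: count, freq, major
    n_excluded: int
    major_min_freq: float


@dataclass
class HaplotypePhenotypeResult:
    gene_id: str
    scope: str
    summary: pd.DataFrame         # index haplotype: n, mean, sd, letters
    anova_f: float
    anova_p: float
    test: str                     # "anova+duncan", "welch_t", "none"


def build_haplotypes(
    g: GenotypeMatrix,
    gene_id: str,
    defining_variants: list,
    major_min_freq: float = 0.05,
) -> HaplotypeTable:
    """Per-accession haplotype over the defining variants (0 -> ref, 2 -> alt)."""
    if not defining_variants:
        raise ValueError(f"{gene_id}: no defining variants")
    order = sorted(defining_variants, key=lambda v: int(g.variants.loc[v, "pos"]))
    cols = [g.variants.index.get_loc(v) for v in order]
    d = g.dosage[:, cols]
    ok = np.all((d == 0) | (d == 2), axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("build_haplotypes %s: %d accessions excluded (het/missing)",
                    gene_id, n_excluded)
    codes = np.where(d == 2, "A", "R")
    haps = ["".join(row) for row in codes]
    assignments = pd.Series(
        [h if keep else None for h, keep in zip(haps, ok)],
        index=g.accession_ids, dtype=object,
    ).dropna()
    counts = assignments.value_counts()
    freq = counts / counts.sum()
    classes = pd.DataFrame({"count": counts, "freq": freq, "major": freq >= major_min_freq})
    return HaplotypeTable(
        gene_id=gene_id, defining_variants=order, assignments=assignments,
        classes=classes, n_excluded=n_excluded, major_min_freq=major_min_freq,
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def _duncan_letters(means: pd.Series, ns: pd.Series, mse: float, df_err: int,
                    alpha: float) -> pd.Series:
    """Letter groups by Duncan's multiple-range procedure.

    Means sorted descending; the critical range for a span of p means is
    q_{1-(1-alpha)^(p-1)}(p, df) * sqrt(MSE / n_h), n_h the harmonic mean of
    the two end groups' sizes. Two means differ when their gap exceeds the
    critical range and no wider non-significant span covers them. Letters
    are assigned greedily from maximal non-significant runs.
    """
    order = means.sort_values(ascending=False).index
    k = len(order)
    m = means[order].to_numpy()
    n = ns[order].to_numpy()

    def crit(p_span, n_a, n_b):
        protection = 1.0 - (1.0 - alpha) ** (p_span - 1)
        q = stats.studentized_range.ppf(1.0 - protection, p_span, df_err)
        n_h = 2.0 / (1.0 / n_a + 1.0 / n_b)
        return q * np.sqrt(mse / n_h)

    # maximal runs [i..j] whose end-to-end gap is below the critical range
    nonsig_runs = []
    for i in range(k):
        j_max = i
        for j in range(i + 1, k):
            if m[i] - m[j] <= crit(j - i + 1, n[i], n[j]):
                j_max = j
            else:
                break
        nonsig_runs.append((i, j_max))
    # drop runs contained in earlier runs
    runs = []
    for i, j in nonsig_runs:
        if not any(a <= i and j <= b for a, b in runs):
            runs.append((i, j))

    letters = ["" for _ in range(k)]
    for r_idx, (i, j) in enumerate(runs):
        letter = chr(ord("a") + r_idx)
        for t in range(i, j + 1):
            letters[t] += letter
    return pd.Series(letters, index=order)


def anova_duncan(
    h: HaplotypeTable,
    pheno: PhenotypeTable,
    trait: str,
    scope: str | None = None,
    scope_column: str = "subpop",
    alpha: float = 0.05,
    min_n: int = 3,
) -> HaplotypePhenotypeResult:
    """Test phenotype differences among major haplotype classes.

    ``scope`` restricts to accessions whose ``scope_column`` label equals it
    (e.g. "japonica"). Requires >= 2 major classes with n >= min_n inside
    the scope. Duncan letters are produced only when the global ANOVA is
    significant at alpha (protected test); otherwise all classes share "a".
    """
    acc = h.assignments.index.intersection(pheno.table.index)
    sub = pheno.table.loc[acc]
    if scope is not None:
        sub = sub[sub[scope_column] == scope]
    y = sub[trait].dropna()
    haps = h.assignments.loc[y.index]
    major = set(h.classes.index[h.classes["major"]])
    keep = haps.isin(major)
    y, haps = y[keep], haps[keep]

    groups = {hap: y[haps == hap] for hap in sorted(haps.unique())}
    groups = {hap: v for hap, v in groups.items() if len(v) >= min_n}
    scope_name = scope or "whole"
    if len(groups) < 2:
        raise ValueError(
            f"{h.gene_id}/{scope_name}: need >= 2 major haplotypes with n >= {min_n}"
        )

    summary = pd.DataFrame(
        {
            "n": {k: len(v) for k, v in groups.items()},
            "mean": {k: float(v.mean()) for k, v in groups.items()},
            "sd": {k: float(v.std(ddof=1)) for k, v in groups.items()},
        }
    )

    values = [v.to_numpy() for v in groups.values()]
    if np.ptp(np.concatenate(values)) == 0:
        summary["letters"] = "a"
        return HaplotypePhenotypeResult(h.gene_id, scope_name, summary,
                                        np.nan, np.nan, "none")

    if len(groups) == 2:
        a, b = values
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        f, anova_p = stats.f_oneway(*values)
        letters = pd.Series(["a", "a"], index=summary.index)
        if p < alpha:
            hi = summary["mean"].idxmax()
            letters[:] = "b"
            letters[hi] = "a"
        summary["letters"] = letters
        return HaplotypePhenotypeResult(h.gene_id, scope_name, summary,
                                        float(f), float(p), "welch_t")

    f, p = stats.f_oneway(*values)
    n_tot = sum(len(v) for v in values)
    df_err = n_tot - len(groups)
    mse = sum(((v - v.mean()) ** 2).sum() for v in values) / df_err
    if p < alpha and mse > 0:
        letters = _duncan_letters(summary["mean"], summary["n"], mse, df_err, alpha)
        summary["letters"] = letters.reindex(summary.index)
        test = "anova+duncan"
    else:
        summary["letters"] = "a"
        test = "anova+duncan" if mse > 0 else "none"
    return HaplotypePhenotypeResult(h.gene_id, scope_name, summary, float(f), float(p), test)


# ---------------------------------------------------------------------------
# deferred-candidate resolution
# ---------------------------------------------------------------------------

def finalize_deferred_candidates(candidates: list, haplotype_results: dict,
                                 alpha: float = 0.05) -> list:
    """Promote deferred genes whose haplotype test is significant in any scope.

    ``haplotype_results``: gene id -> list of HaplotypePhenotypeResult. The
    input list is returned with statuses updated in place (same objects).
    """
    for cg in candidates:
        if cg.status != "deferred":
            continue
        results = haplotype_results.get(cg.gene_id, [])
        if any(np.isfinite(r.anova_p) and r.anova_p < alpha for r in results):
            cg.status = "candidate"
        else:
            cg.status = "excluded"
    return candidates
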