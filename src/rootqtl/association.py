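"""Structure-aware genome scans: PCA, kinship, GLM and a compressed mixed model.

The fixed-effects scan (GLM) regresses the trait on each variant's dosage
with principal-component covariates. The mixed-model scan (MLM) adds a
polygenic random effect with covariance proportional to a VanRaden kinship
matrix; the variance ratio is estimated once by REML on the null model via
the spectral decomposition of K and reused for every variant (the P3D
shortcut), optionally after compressing accessions into kinship-clustered
groups (CMLM-style).

Missing dosages are mean-imputed per variant for association only.
Monomorphic (zero-variance) variants are flagged untested with NaN results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from .io_model import GenotypeMatrix, MISSING


@dataclass
class StructureModel:
    pcs: np.ndarray | None = None        # (n, k) scores, variance-sorted
    kinship: np.ndarray | None = None    # (n, n) symmetric PSD
    accession_ids: list | None = None
    groups: np.ndarray | None = None     # compression grouping (n,) int labels


@dataclass
class AssociationResult:
    variants: pd.DataFrame        # copy of the variant table
    beta: np.ndarray
    se: np.ndarray
    minus_log10_p: np.ndarray
    tested: np.ndarray            # bool; False = monomorphic/collinear
    model: str                    # "glm" or "mlm"
    n_used: int

    def to_frame(self) -> pd.DataFrame:
        out = self.variants.copy()
        out["beta"] = self.beta
        out["se"] = self.se
        out["minus_log10_p"] = self.minus_log10_p
        out["tested"] = self.tested
        out["model"] = self.model
        return out


# ---------------------------------------------------------------------------
# dosage preparation
# ---------------------------------------------------------------------------

def imputed_dosage(g: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """Float dosage matrix with per-variant mean imputation of missing calls."""
    d = g.dosage if rows is None else g.dosage[rows, :]
    x = d.astype(float)
    x[d == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    idx = np.where(np.isnan(x))
    x[idx] = mean[idx[1]]
    return x


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def compute_pcs(g: GenotypeMatrix, k: int = 3, rows: np.ndarray | None = None) -> StructureModel:
    """Principal-component scores of the column-standardized dosage matrix."""
    n = g.n_accessions if rows is None else len(rows)
    if k >= n:
        raise ValueError(f"k={k} PCs require more than {n} accessions")
    x = imputed_dosage(g, rows)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    ids = g.accession_ids if rows is None else [g.accession_ids[i] for i in rows]
    return StructureModel(pcs=scores, accession_ids=list(ids))


def compute_kinship(g: GenotypeMatrix, rows: np.ndarray | None = None) -> StructureModel:
    """VanRaden method-1 kinship: ZZ' / sum(2 p (1-p)) on 2p-centered dosages."""
    n = g.n_accessions if rows is None else len(rows)
    if n < 2:
        raise ValueError("kinship needs at least 2 accessions")
    d = g.dosage if rows is None else g.dosage[rows, :]
    if (d == MISSING).all(axis=1).any():
        bad = np.flatnonzero((d == MISSING).all(axis=1))[0]
        raise ValueError(f"accession index {bad} has no called genotypes")
    x = imputed_dosage(g, rows)
    p = x.mean(axis=0) / 2.0
    z = x - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all variants monomorphic; kinship undefined")
    k = z @ z.T / denom
    ids = g.accession_ids if rows is None else [g.accession_ids[i] for i in rows]
    return StructureModel(kinship=(k + k.T) / 2.0, accession_ids=list(ids))


def genomic_inflation(minus_log10_p: np.ndarray) -> float:
    """Median-based lambda: observed vs expected median 1-df chi-square."""
    p = np.power(10.0, -np.asarray(minus_log10_p, dtype=float))
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# scan core: residualized per-variant regression
# ---------------------------------------------------------------------------

def _scan_core(x: np.ndarray, y: np.ndarray, covar: np.ndarray, model: str,
               variants: pd.DataFrame) -> AssociationResult:
    """Per-variant OLS of y on [covar, x_j]; exact via Frisch–Waugh residualization.

    ``covar`` must include the intercept column. df = n - covar columns - 1.
    """
    n, m = x.shape
    q, _ = np.linalg.qr(covar)
    y_r = y - q @ (q.T @ y)
    x_r = x - q @ (q.T @ x)
    ss_x = (x_r**2).sum(axis=0)
    tested = ss_x > 1e-12 * n
    ss_x_safe = np.where(tested, ss_x, 1.0)
    beta = (x_r * y_r[:, None]).sum(axis=0) / ss_x_safe
    df = n - covar.shape[1] - 1
    sse = (y_r**2).sum() - beta**2 * ss_x_safe
    sse = np.maximum(sse, 0.0)
    sigma2 = sse / df
    se = np.sqrt(np.where(tested, sigma2 / ss_x_safe, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    logp = -(stats.t.logsf(np.abs(t), df) + np.log(2.0)) / np.log(10.0)
    beta = np.where(tested, beta, np.nan)
    logp = np.where(tested, logp, np.nan)
    return AssociationResult(
        variants=variants.copy(), beta=beta, se=se, minus_log10_p=logp,
        tested=tested, model=model, n_used=n,
    )


def _align(g: GenotypeMatrix, pheno, trait: str):
    """Rows of g with a finite trait value, plus the trait vector."""
    ids = [a for a in g.accession_ids if a in pheno.table.index]
    y = pheno.trait(trait, ids)
    ok = np.isfinite(y)
    ids = [a for a, keep in zip(ids, ok) if keep]
    rows = g.accession_index(ids)
    return rows, y[ok], ids


def scan_glm(g: GenotypeMatrix, pheno, trait: str, structure: StructureModel | None = None,
             k_pcs: int = 3) -> AssociationResult:
    """Fixed-effects scan: y = mu + PCs + dosage*beta + e, two-sided t test on beta."""
    rows, y, ids = _align(g, pheno, trait)
    if structure is None or structure.pcs is None:
        structure = compute_pcs(g, k=k_pcs, rows=rows)
        pcs = structure.pcs
    else:
        order = {a: i for i, a in enumerate(structure.accession_ids)}
        pcs = structure.pcs[[order[a] for a in ids], :]
    x = imputed_dosage(g, rows)
    covar = np.column_stack([np.ones(len(y)), pcs])
    if np.linalg.matrix_rank(covar) < covar.shape[1]:
        raise ValueError("collinear covariate matrix (rank-deficient PCs)")
    return _scan_core(x, y, covar, "glm", g.variants)


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def _reml_h2(yt: np.ndarray, xt: np.ndarray, lam: np.ndarray) -> tuple:
    """REML estimate of h = sg2/(sg2+se2) on the eigen-rotated null model.

    Returns (h, log restricted likelihood at h).
    """
    n, p = xt.shape

    def negloglik(h):
        v = h * lam + (1.0 - h)
        w = 1.0 / v
        xtw = xt * w[:, None]
        xx = xt.T @ xtw
        xy = xtw.T @ yt
        try:
            beta = np.linalg.solve(xx, xy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - xt @ beta
        rss = float(r @ (w * r))
        sign, logdet_xx = np.linalg.slogdet(xx)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * np.log(rss / (n - p))
            + np.sum(np.log(v))
            + logdet_xx
            + (n - p)
        )
        return -ll

    res = minimize_scalar(negloglik, bounds=(1e-6, 1 - 1e-6), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x), -float(res.fun)


def _compress_kinship(k: np.ndarray, n_groups: int, seed_linkage=None) -> tuple:
    """Cluster accessions on kinship distance; replace K by group-mean blocks."""
    n = k.shape[0]
    if n_groups >= n:
        return k, np.arange(n)
    dist = np.max(k) - k
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=n_groups, criterion="maxclust") - 1
    kc = np.zeros_like(k)
    uniq = np.unique(labels)
    for a in uniq:
        ia = labels == a
        for b in uniq:
            ib = labels == b
            kc[np.ix_(ia, ib)] = k[np.ix_(ia, ib)].mean()
    return (kc + kc.T) / 2.0, labels


def scan_mlm(g: GenotypeMatrix, pheno, trait: str, structure: StructureModel,
             compression_level: int | None = None) -> AssociationResult:
    """Kinship mixed-model scan with the variance ratio fixed from the null model.

    ``compression_level`` = number of accession groups; ``None`` or >= n
    disables compression (one group per accession). ``compression_level=0``
    selects the group count from the grid {n, n/2, n/4} by null-model REML
    likelihood.
    """
    if structure.kinship is None:
        raise ValueError("scan_mlm requires a kinship matrix in the structure model")
    rows, y, ids = _align(g, pheno, trait)
    order = {a: i for i, a in enumerate(structure.accession_ids)}
    sel = [order[a] for a in ids]
    k = structure.kinship[np.ix_(sel, sel)]
    pcs = structure.pcs[sel, :] if structure.pcs is not None else None
    n = len(y)

    covar = np.ones((n, 1)) if pcs is None else np.column_stack([np.ones(n), pcs])

    def eig_psd(kmat):
        lam, u = np.linalg.eigh(kmat)
        return np.clip(lam, 0.0, None), u

    if compression_level == 0:
        best = None
        for ng in {n, max(2, n // 2), max(2, n // 4)}:
            kc, labels = _compress_kinship(k, ng)
            lam, u = eig_psd(kc)
            h, ll = _reml_h2(u.T @ y, u.T @ covar, lam)
            if best is None or ll > best[0]:
                best = (ll, kc, labels)
        _, k_used, groups = best
    elif compression_level is not None and compression_level < n:
        k_used, groups = _compress_kinship(k, compression_level)
    else:
        k_used, groups = k, np.arange(n)

    lam, u = eig_psd(k_used)
    yt = u.T @ y
    ct = u.T @ covar
    h, _ = _reml_h2(yt, ct, lam)
    v = h * lam + (1.0 - h)
    w = 1.0 / np.sqrt(v)

    x = imputed_dosage(g, rows)
    xt = (u.T @ x) * w[:, None]
    res = _scan_core(xt, yt * w, ct * w[:, None], "mlm", g.variants)
    return res
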