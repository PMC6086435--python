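"""Conditional permutation test for the genome-wide significance threshold.

The trait Y is split into a structure component P (least-squares fit of Y on
the PC covariates, intercept included) and a residual genotypic component
G = Y - P. Each permutation reshuffles G to Gr, reconstructs P + Gr, rescans
a pre-filtered variant set with the same model and covariates, and records
the genome-wide maximum -log10(p). The threshold is a percentile (default
95) of those per-permutation maxima — the study-wide maximum-statistic
convention. A pooled-statistic variant (percentile of all permuted
statistics) is available for comparison.

Pre-filtering to variants with original -log10(p) >= 2 mirrors the
efficiency shortcut of the published protocol; maxima that would fall below
that cutoff are truncated, which is immaterial for thresholds above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import (
    AssociationResult,
    StructureModel,
    _align,
    _reml_h2,
    imputed_dosage,
)
from .io_model import GenotypeMatrix, logger


@dataclass
class PermutationDecomposition:
    y: np.ndarray
    structure_component: np.ndarray   # P: fitted values on the PCs
    genotypic_component: np.ndarray   # G = Y - P

    def reconstruct(self, permuted_g: np.ndarray) -> np.ndarray:
        return self.structure_component + permuted_g


@dataclass
class ThresholdResult:
    threshold: float
    maxima: np.ndarray
    percentile: float
    n_perm: int
    prefilter: float
    seed: int
    model: str
    convention: str  # "maxima" or "pooled"

    def to_dict(self) -> dict:
        hist, edges = np.histogram(self.maxima, bins=20)
        return {
            "threshold": self.threshold,
            "percentile": self.percentile,
            "n_perm": self.n_perm,
            "prefilter": self.prefilter,
            "seed": self.seed,
            "model": self.model,
            "convention": self.convention,
            "maxima_hist": {"counts": hist.tolist(), "edges": edges.tolist()},
        }


def decompose(y: np.ndarray, pcs: np.ndarray) -> PermutationDecomposition:
    """P = fitted values of Y on [1, PCs] jointly; G = residuals.

    ``marginal=True`` behaviour (summing per-PC simple regressions) is in
    :func:`decompose_marginal`; joint regression is the default reading of
    "average effect of each PC ... through regression".
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing trait values among scanned accessions")
    x = np.column_stack([np.ones(len(y)), pcs])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient PC matrix")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    p = x @ coef
    return PermutationDecomposition(y=y, structure_component=p, genotypic_component=y - p)


def decompose_marginal(y: np.ndarray, pcs: np.ndarray) -> PermutationDecomposition:
    """Fidelity option: P = mean(Y) + sum of per-PC simple-regression fits."""
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing trait values among scanned accessions")
    yc = y - y.mean()
    p = np.full_like(y, y.mean())
    for j in range(pcs.shape[1]):
        xj = pcs[:, j] - pcs[:, j].mean()
        ss = float(xj @ xj)
        if ss == 0:
            raise ValueError(f"constant PC column {j}")
        p = p + xj * (float(xj @ yc) / ss)
    return PermutationDecomposition(y=y, structure_component=p, genotypic_component=y - p)


def _max_logp_batch(x_r: np.ndarray, ss_x: np.ndarray, tested: np.ndarray,
                    y_r: np.ndarray, df: int) -> np.ndarray:
    """Genome-wide max -log10(p) for a batch of (already residualized) phenotypes.

    x_r: (n, m) residualized dosages; y_r: (n, B) residualized phenotypes.
    Returns (B,) maxima. p is monotone in |t|, and |t| is monotone in
    beta^2*ss_x/sse, so the per-permutation maximum is located on that
    statistic and only converted to -log10(p) once.
    """
    from scipy import stats

    num = x_r.T @ y_r                      # (m, B)
    ss_y = (y_r**2).sum(axis=0)            # (B,)
    ss_x_safe = np.where(tested, ss_x, np.inf)[:, None]
    expl = num**2 / ss_x_safe              # beta^2 * ss_x
    sse = np.maximum(ss_y[None, :] - expl, 1e-300)
    f = expl * df / sse                    # t^2
    f_max = f.max(axis=0)
    t_max = np.sqrt(f_max)
    return -(stats.t.logsf(t_max, df) + np.log(2.0)) / np.log(10.0)


def conditional_threshold(
    g: GenotypeMatrix,
    pheno,
    trait: str,
    structure: StructureModel,
    scan: AssociationResult,
    model: str = "mlm",
    n_perm: int = 1000,
    percentile: float = 95.0,
    prefilter: float = 2.0,
    seed: int = 0,
    batch: int = 200,
    convention: str = "maxima",
) -> ThresholdResult:
    """Conditional-permutation genome-wide threshold on the -log10(p) scale.

    ``scan`` is the association result on the observed phenotype; variants
    with -log10(p) >= ``prefilter`` form the rescanned set (falls back to
    all tested variants when empty). ``model`` must match the scan model.
    """
    if model not in ("glm", "mlm"):
        raise ValueError(f"unknown model {model!r}")
    rows, y, ids = _align(g, pheno, trait)
    order = {a: i for i, a in enumerate(structure.accession_ids)}
    sel = [order[a] for a in ids]
    pcs = structure.pcs[sel, :]
    dec = decompose(y, pcs)
    # a trait fully explained by structure leaves G = 0 up to float noise;
    # snap it so every permutation reconstructs the identical phenotype
    if np.ptp(dec.genotypic_component) <= 1e-10 * max(1.0, float(np.std(y))):
        dec.genotypic_component = np.zeros_like(dec.genotypic_component)

    keep = scan.tested & (scan.minus_log10_p >= prefilter)
    if not keep.any():
        logger.warning("conditional_threshold: prefilter %.1f left no variants; using all", prefilter)
        keep = scan.tested.copy()
    x = imputed_dosage(g, rows)[:, keep]
    n = len(y)
    covar = np.column_stack([np.ones(n), pcs])

    if model == "mlm":
        if structure.kinship is None:
            raise ValueError("mlm threshold requires kinship")
        k = structure.kinship[np.ix_(sel, sel)]
        lam, u = np.linalg.eigh(k)
        lam = np.clip(lam, 0.0, None)
        h, _ = _reml_h2(u.T @ y, u.T @ covar, lam)
        w = 1.0 / np.sqrt(h * lam + (1.0 - h))
        rot = u.T * w[:, None]            # maps a phenotype to the whitened basis
        x_w = rot @ x
        covar_w = rot @ covar
    else:
        rot = None
        x_w = x
        covar_w = covar

    q, _ = np.linalg.qr(covar_w)
    x_r = x_w - q @ (q.T @ x_w)
    ss_x = (x_r**2).sum(axis=0)
    tested = ss_x > 1e-12 * n
    df = n - covar_w.shape[1] - 1

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    pooled: list = []
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.empty((n, b))
        for j in range(b):
            perms[:, j] = dec.reconstruct(rng.permutation(dec.genotypic_component))
        if rot is not None:
            perms = rot @ perms
        y_r = perms - q @ (q.T @ perms)
        if convention == "pooled":
            from scipy import stats

            num = x_r.T @ y_r
            ss_y = (y_r**2).sum(axis=0)
            ss_x_safe = np.where(tested, ss_x, np.inf)[:, None]
            expl = num**2 / ss_x_safe
            sse = np.maximum(ss_y[None, :] - expl, 1e-300)
            t = np.sqrt(expl * df / sse)
            logp = -(stats.t.logsf(t, df) + np.log(2.0)) / np.log(10.0)
            pooled.append(logp[tested, :].ravel())
            maxima[done : done + b] = logp[tested, :].max(axis=0)
        else:
            maxima[done : done + b] = _max_logp_batch(x_r, ss_x, tested, y_r, df)
        done += b

    if convention == "pooled":
        threshold = float(np.percentile(np.concatenate(pooled), percentile, method="higher"))
    else:
        threshold = float(np.percentile(maxima, percentile, method="higher"))
    return ThresholdResult(
        threshold=threshold,
        maxima=maxima,
        percentile=percentile,
        n_perm=n_perm,
        prefilter=prefilter,
        seed=seed,
        model=model,
        convention=convention,
    )
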