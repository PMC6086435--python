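"""Adaptation scan over candidate-gene regions.

Per gene region and accession group: nucleotide diversity pi, Watterson's
theta and Tajima's D from SNP-table data (no invariant-site resequencing),
diversity-ratio selection flags (ratio > 4), trait-increasing-allele
pyramiding frequencies, ancestral-allele presence in the wild group, and a
neighbor-joining tree from candidate-gene SNPs with a monophyly check.

Diversity conventions: per-site pi contribution 2*p*(1-p)*n/(n-1) with
site-wise n under pairwise deletion; region pi = sum over variant sites /
region length L (monomorphic sites contribute 0). theta_W = S / a1 / L with
a1 evaluated at the harmonic-mean n over segregating sites. Tajima's D uses
the 1989 beta-coefficient variance constants at that same n. Absolute pi
and theta depend on the L convention; the ratio statistics do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import GenotypeMatrix, MISSING


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityReport:
    gene_id: str
    group: str
    pi: float           # per site
    theta_w: float      # per site
    tajima_d: float     # NaN when S == 0 or n < 4
    s: int              # segregating sites used
    n: float            # harmonic-mean sequences per used site
    length: int


def _tajima_constants(n: float) -> dict:
    """Tajima (1989) variance constants; n may be fractional (harmonic-mean
    sample size under pairwise deletion), in which case the harmonic sums
    a1 = sum 1/i and a2 = sum 1/i^2 (i = 1..n-1) are evaluated through the
    digamma/trigamma continuation, which coincides with the sums at integer n.
    """
    from scipy.special import polygamma, digamma

    a1 = float(digamma(n) + np.euler_gamma)
    a2 = float(np.pi**2 / 6.0 - polygamma(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def diversity(
    g: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    accessions: list,
    gene_id: str = "",
    group: str = "",
    min_n: int = 4,
) -> DiversityReport:
    """pi, Watterson's theta and Tajima's D for one region and group.

    Inbred accessions contribute one sequence each (dosage/2, heterozygous
    calls excluded site-wise). Sites with fewer than ``min_n`` called
    sequences are skipped.
    """
    L = end - start + 1
    rows = g.accession_index(accessions)
    mask = g.region_mask(chrom, start, end)
    d = g.dosage[np.ix_(rows, np.flatnonzero(mask))].astype(float)
    d[(d == MISSING) | (d == 1)] = np.nan  # het: ambiguous haploid state
    allele = d / 2.0

    n_site = np.sum(~np.isnan(allele), axis=0).astype(float)
    usable = n_site >= min_n
    pi_sum = 0.0
    seg = 0
    ns = []
    for j in np.flatnonzero(usable):
        col = allele[:, j]
        col = col[~np.isnan(col)]
        n = len(col)
        p = col.mean()
        if 0.0 < p < 1.0:
            seg += 1
            ns.append(n)
            pi_sum += 2.0 * p * (1.0 - p) * n / (n - 1.0)
    pi = pi_sum / L
    if seg == 0:
        return DiversityReport(gene_id, group, 0.0, 0.0, np.nan, 0,
                               float(np.mean(n_site[usable])) if usable.any() else 0.0, L)
    n_harm = seg / np.sum(1.0 / np.asarray(ns, dtype=float))
    if n_harm < min_n:
        return DiversityReport(gene_id, group, pi, np.nan, np.nan, seg, n_harm, L)
    const = _tajima_constants(n_harm)
    theta_w = seg / const["a1"] / L
    var_d = const["e1"] * seg + const["e2"] * seg * (seg - 1.0)
    d_stat = (pi * L - theta_w * L) / np.sqrt(var_d) if var_d > 0 else np.nan
    return DiversityReport(gene_id, group, float(pi), float(theta_w), float(d_stat),
                           seg, float(n_harm), L)


SELECTION_RATIO = 4.0
TAJIMA_FLAG = -1.0


def ratio_scan(reports: dict, pairs: list) -> pd.DataFrame:
    """Diversity-ratio table with selection flags.

    ``reports``: (gene_id, group) -> DiversityReport. ``pairs``: list of
    (numerator_group, denominator_group, label). One row per gene x pair
    with ratio, log2 ratio and the ratio > 4 flag; a zero denominator with
    nonzero numerator is flagged infinite, 0/0 is undefined.
    """
    genes = sorted({k[0] for k in reports})
    rows = []
    for gid in genes:
        for num_g, den_g, label in pairs:
            rn = reports.get((gid, num_g))
            rd = reports.get((gid, den_g))
            if rn is None or rd is None:
                continue
            if rd.pi > 0:
                ratio = rn.pi / rd.pi
                note = ""
            elif rn.pi > 0:
                ratio = np.inf
                note = "zero_denominator"
            else:
                ratio = np.nan
                note = "undefined_0_over_0"
            rows.append(
                {
                    "gene": gid,
                    "ratio_label": label,
                    "pi_num": rn.pi,
                    "pi_den": rd.pi,
                    "ratio": ratio,
                    "log2_ratio": np.log2(ratio) if ratio and np.isfinite(ratio) and ratio > 0 else np.nan,
                    "selected": bool(ratio > SELECTION_RATIO) if not np.isnan(ratio) else False,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele pyramiding
# ---------------------------------------------------------------------------

@dataclass
class PyramidingProfile:
    trait: str
    snp_ids: list
    group_freq: pd.Series          # group -> mean trait-increasing allele frequency
    detected_in_wild: int
    absent_in_wild: int


def pyramiding(
    g: GenotypeMatrix,
    snp_ids: list,
    groups: pd.Series,
    increasing_allele: dict,
    wild_label: str = "wild",
    trait: str = "",
) -> PyramidingProfile:
    """Per-group mean trait-increasing allele frequency over a SNP set.

    ``increasing_allele``: variant id -> "alt"/"ref" (from the GWAS effect
    sign). Detection counts = SNPs at which both alleles seen in cultivated
    groups also segregate in the wild group.
    """
    snp_ids = [v for v in snp_ids if v in g.variants.index]
    if not snp_ids:
        raise ValueError("empty SNP set")
    cols = [g.variants.index.get_loc(v) for v in snp_ids]
    acc = [a for a in g.accession_ids if a in groups.index]
    rows = g.accession_index(acc)
    glab = groups.loc[acc]
    d = g.dosage[np.ix_(rows, cols)].astype(float)
    d[d == MISSING] = np.nan
    inc = np.array([1.0 if increasing_allele[v] == "alt" else -1.0 for v in snp_ids])

    freq = {}
    for grp in sorted(glab.unique()):
        sub = d[(glab == grp).to_numpy(), :]
        with np.errstate(invalid="ignore"):
            f_alt = np.nanmean(sub, axis=0) / 2.0
        f_inc = np.where(inc > 0, f_alt, 1.0 - f_alt)
        freq[grp] = float(np.nanmean(f_inc))

    def alleles_present(rows_block, j):
        col = rows_block[:, j]
        col = col[~np.isnan(col)]
        present = set()
        if np.any(col <= 1):
            present.add("ref")
        if np.any(col >= 1):
            present.add("alt")
        return present

    wild_rows = d[(glab == wild_label).to_numpy(), :]
    cult_rows = d[(glab != wild_label).to_numpy(), :]
    detected = sum(
        1
        for j in range(len(snp_ids))
        if alleles_present(cult_rows, j) <= alleles_present(wild_rows, j)
    )
    return PyramidingProfile(
        trait=trait,
        snp_ids=snp_ids,
        group_freq=pd.Series(freq),
        detected_in_wild=detected,
        absent_in_wild=len(snp_ids) - detected,
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class NJNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (child, branch_length)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return str(self.name)
        inner = ",".join(f"{c._nwk()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class NJTree:
    root: NJNode
    leaf_names: list

    def newick(self) -> str:
        return self.root.newick()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def ibs_distance(g: GenotypeMatrix, snp_ids: list | None = None,
                 accessions: list | None = None) -> tuple:
    """Identity-by-state mismatch proportion with pairwise deletion.

    Distance between two accessions = mean over shared called variants of
    |dosage_i - dosage_j| / 2. Raises if a pair shares no called variant.
    """
    acc = accessions if accessions is not None else list(g.accession_ids)
    rows = g.accession_index(acc)
    if snp_ids is not None:
        cols = [g.variants.index.get_loc(v) for v in snp_ids if v in g.variants.index]
        d = g.dosage[np.ix_(rows, cols)].astype(float)
    else:
        d = g.dosage[rows, :].astype(float)
    d[d == MISSING] = np.nan
    n = len(acc)
    called = ~np.isnan(d)
    shared = called.astype(float) @ called.astype(float).T
    off_diag_empty = (shared == 0) & ~np.eye(n, dtype=bool)
    if off_diag_empty.any():
        i, j = np.argwhere(off_diag_empty)[0]
        raise ValueError(f"accessions {acc[i]!r} and {acc[j]!r} share no called SNP")
    # |di - dj| over {0,1,2} dosages decomposes on indicator matrices:
    # 2 for 0-vs-2 pairs, 1 for pairs involving a heterozygote
    a0 = (np.nan_to_num(d, nan=-9) == 0).astype(float)
    a1 = (np.nan_to_num(d, nan=-9) == 1).astype(float)
    a2 = (np.nan_to_num(d, nan=-9) == 2).astype(float)
    mism = 2.0 * (a0 @ a2.T) + (a0 @ a1.T) + (a1 @ a2.T)
    mism = mism + mism.T
    dist = mism / np.maximum(shared, 1.0) / 2.0
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0, acc


def nj_tree(dist: np.ndarray, names: list) -> NJTree:
    """Saitou–Nei neighbor joining.

    Q-matrix minimization with ties broken by the lowest index pair;
    negative branch lengths clipped to 0. Exact on additive distances.
    """
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = np.asarray(dist, dtype=float).copy()
    nodes = [NJNode(name=str(nm)) for nm in names]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2.0) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # argmin returns first (lowest index pair) on ties
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2.0))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = NJNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_loc, k in enumerate(active):
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[new_idx, k] = d[k, new_idx] = max(dk, 0.0)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j = active
    root = NJNode(children=[(nodes[i], max(d[i, j], 0.0) / 2.0),
                            (nodes[j], max(d[i, j], 0.0) / 2.0)])
    # final join shown as a midpoint-rooted cherry of the last two lineages;
    # the tree is to be read as unrooted
    return NJTree(root=root, leaf_names=[str(nm) for nm in names])


def parse_newick(text: str) -> NJNode:
    """Minimal Newick parser for trees written by :class:`NJTree`."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node():
        nonlocal pos
        node = NJNode()
        if text[pos] == "(":
            pos += 1
            while True:
                child = parse_node()
                bl = 0.0
                if pos < len(text) and text[pos] == ":":
                    pos += 1
                    start = pos
                    while pos < len(text) and text[pos] not in ",()":
                        pos += 1
                    bl = float(text[start:pos])
                node.children.append((child, bl))
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ":,()":
            pos += 1
        name = text[start:pos]
        if name:
            node.name = name
        return node

    return parse_node()


def tree_splits(root: NJNode) -> list:
    """Leaf sets of every internal edge (clades of the rooted form)."""
    out = []

    def walk(node):
        if node.is_leaf():
            return [node.name]
        leaves = []
        for c, _ in node.children:
            leaves.extend(walk(c))
        out.append(frozenset(leaves))
        return leaves

    walk(root)
    return out


def monophyly_check(tree: NJTree, labels: set) -> dict:
    """Smallest unrooted-tree side containing all labelled leaves.

    Evaluates every split of the tree (both sides of each edge) and returns
    the minimal leaf set covering ``labels``, its purity (labelled/total)
    and whether the labelled set is perfectly clustered.
    """
    labels = set(labels)
    if not labels:
        raise ValueError("empty label set")
    all_leaves = set(tree.root.leaves())
    unknown = labels - all_leaves
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)[:3]}")
    sides = [frozenset({leaf}) for leaf in all_leaves] + tree_splits(tree.root)
    candidates = [all_leaves]
    for side in sides:
        for s in (set(side), all_leaves - set(side)):
            if labels <= s:
                candidates.append(s)
    best = min(candidates, key=len)
    purity = len(labels) / len(best)
    return {"is_clustered": purity == 1.0, "clade": best, "purity": purity}
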