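"""QTL calling from clustered significant variants, cross-population
comparison, and intersection with external linkage-mapping intervals.

A QTL is a chain of >= ``min_snps`` significant variants on one chromosome
in which adjacent members are <= ``window_bp`` apart (single-linkage gap
chaining; default 170 kb, matching LD-decay-scale clustering). The QTL span
is the min..max of member positions, with no flanking extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import GenotypeMatrix, LinkageQTLTable, MISSING, logger
from .association import AssociationResult


@dataclass
class QTLInterval:
    qtl_id: str
    chrom: str
    start: int
    end: int
    member_ids: list
    peak_id: str
    peak_pos: int
    peak_logp: float
    population: str = "whole"
    trait: str = ""

    def __post_init__(self) -> None:
        if len(self.member_ids) < 3:
            raise ValueError(f"{self.qtl_id}: QTL needs >= 3 member variants")
        if not (self.start <= self.peak_pos <= self.end):
            raise ValueError(f"{self.qtl_id}: peak outside span")

    def span(self) -> int:
        return self.end - self.start + 1


def call_qtls(
    res: AssociationResult,
    threshold: float,
    window_bp: int = 170_000,
    min_snps: int = 3,
    population: str = "whole",
    trait: str = "",
) -> list:
    """Chain significant variants (gap <= window_bp) into QTL intervals.

    Deterministic and invariant to input variant order: variants are sorted
    by (chrom, pos) before chaining.
    """
    sig = res.tested & (res.minus_log10_p >= threshold)
    v = res.variants.loc[sig].copy()
    v["minus_log10_p"] = res.minus_log10_p[sig]
    v = v.sort_values(["chrom", "pos"], kind="mergesort")

    qtls: list = []
    counter = 0
    for chrom, sub in v.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window_bp)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            if e - s + 1 < min_snps:
                continue
            chunk = sub.iloc[s : e + 1]
            counter += 1
            peak = chunk["minus_log10_p"].idxmax()
            qtls.append(
                QTLInterval(
                    qtl_id=f"q{trait or 'QTL'}{counter}_{population}",
                    chrom=chrom,
                    start=int(chunk["pos"].iloc[0]),
                    end=int(chunk["pos"].iloc[-1]),
                    member_ids=list(chunk.index),
                    peak_id=peak,
                    peak_pos=int(chunk.loc[peak, "pos"]),
                    peak_logp=float(chunk.loc[peak, "minus_log10_p"]),
                    population=population,
                    trait=trait,
                )
            )
    return qtls


def qtls_to_frame(qtls: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "qtl_id": q.qtl_id,
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "n_snps": len(q.member_ids),
                "peak_pos": q.peak_pos,
                "peak_logp": q.peak_logp,
                "population": q.population,
                "trait": q.trait,
            }
            for q in qtls
        ]
    )


def write_qtls_bed(qtls: list, path) -> None:
    """BED export (0-based half-open)."""
    with open(path, "w") as fh:
        for q in qtls:
            fh.write(f"{q.chrom}\t{q.start - 1}\t{q.end}\t{q.qtl_id}\t{len(q.member_ids)}\n")


# ---------------------------------------------------------------------------
# cross-population comparison
# ---------------------------------------------------------------------------

def overlap_qtls(a: list, b: list, slack_bp: int = 0) -> pd.DataFrame:
    """All-pairs comparison of two QTL lists of the same trait.

    Pairs whose spans intersect after widening by ``slack_bp`` are
    ``identical`` when the raw spans intersect, else ``nearby``. QTLs of
    either list with no partner at all are reported as ``unique`` rows with
    the other side blank and the distance to the closest same-chromosome
    interval.
    """
    rows = []
    matched_a, matched_b = set(), set()
    for qa in a:
        for qb in b:
            if qa.chrom != qb.chrom:
                continue
            gap = max(qb.start - qa.end, qa.start - qb.end, 0)
            if gap == 0:
                cls = "identical"
            elif gap <= slack_bp:
                cls = "nearby"
            else:
                continue
            rows.append(
                {"a": qa.qtl_id, "b": qb.qtl_id, "chrom": qa.chrom,
                 "class": cls, "distance_bp": gap}
            )
            matched_a.add(qa.qtl_id)
            matched_b.add(qb.qtl_id)

    def nearest(q, others):
        gaps = [
            max(o.start - q.end, q.start - o.end, 0)
            for o in others
            if o.chrom == q.chrom
        ]
        return min(gaps) if gaps else np.nan

    for qa in a:
        if qa.qtl_id not in matched_a:
            rows.append({"a": qa.qtl_id, "b": "", "chrom": qa.chrom,
                         "class": "unique", "distance_bp": nearest(qa, b)})
    for qb in b:
        if qb.qtl_id not in matched_b:
            rows.append({"a": "", "b": qb.qtl_id, "chrom": qb.chrom,
                         "class": "unique", "distance_bp": nearest(qb, a)})
    return pd.DataFrame(rows, columns=["a", "b", "chrom", "class", "distance_bp"])


# ---------------------------------------------------------------------------
# linkage-mapping intersection
# ---------------------------------------------------------------------------

def intersect_linkage(
    qtls: list,
    linkage: LinkageQTLTable,
    g: GenotypeMatrix,
    sig_variant_ids: list,
    trait: str | None = None,
) -> pd.DataFrame:
    """Significant variants inside GWAS-QTL x linkage-interval overlaps whose
    cross parents carry different, non-missing genotypes.

    Returns a frame (variant id, qtl_id, linkage row index, parent dosages).
    Variants with missing or equal parental genotypes are dropped (logged).
    """
    table = linkage.table if trait is None else linkage.for_trait(trait)
    for col in ("parent1", "parent2"):
        for parent in table[col].unique():
            if parent not in g.accession_ids:
                raise KeyError(f"linkage parent {parent!r} absent from genotype matrix")

    vt = g.variants
    rows = []
    for vid in sig_variant_ids:
        if vid not in vt.index:
            continue
        chrom = vt.loc[vid, "chrom"]
        pos = int(vt.loc[vid, "pos"])
        in_qtl = [q for q in qtls if q.chrom == chrom and q.start <= pos <= q.end]
        if not in_qtl:
            continue
        vcol = vt.index.get_loc(vid)
        for li, lrow in table.iterrows():
            if lrow["chrom"] != chrom or not (lrow["start"] <= pos <= lrow["end"]):
                continue
            p1 = int(g.dosage[g.accession_index([lrow["parent1"]])[0], vcol])
            p2 = int(g.dosage[g.accession_index([lrow["parent2"]])[0], vcol])
            if p1 == MISSING or p2 == MISSING:
                logger.info("intersect_linkage: %s dropped (missing parent call)", vid)
                continue
            if p1 == p2:
                continue
            rows.append(
                {"variant": vid, "qtl_id": in_qtl[0].qtl_id, "linkage_row": li,
                 "parent1_dosage": p1, "parent2_dosage": p2}
            )
    return pd.DataFrame(
        rows, columns=["variant", "qtl_id", "linkage_row", "parent1_dosage", "parent2_dosage"]
    )


def qtls_with_linkage_coverage(qtls: list, linkage: LinkageQTLTable, trait: str | None = None) -> set:
    """IDs of GWAS QTLs overlapped by at least one linkage interval."""
    table = linkage.table if trait is None else linkage.for_trait(trait)
    out = set()
    for q in qtls:
        for _, lrow in table.iterrows():
            if lrow["chrom"] == q.chrom and lrow["start"] <= q.end and lrow["end"] >= q.start:
                out.add(q.qtl_id)
                break
    return out
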