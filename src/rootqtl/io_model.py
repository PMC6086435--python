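"""Shared data model and file IO for the root-QTL pipeline.

Containers for genotypes, phenotypes, gene models and expression data, the
variant-QC filters (missing rate / MAF / LD pruning) applied before any
structure or association analysis, and readers/writers for the standard
formats (VCF v4.2, GFF3, FASTA, TSV tables).

Conventions
-----------
* Coordinates are 1-based inclusive everywhere (VCF/GFF3 native).
* Dosages count ALT-allele copies: 0, 1, 2; -1 marks a missing call.
  Half-calls and ``./.`` become missing on read.
* MAF is computed on allele copies (two per called genotype), missing
  genotypes excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("rootqtl")

MISSING = -1

PROMOTER_BP = 2000  # upstream of the strand-aware TSS


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Accession x variant allele-dosage table.

    Parameters
    ----------
    accession_ids : list of str
    variants : DataFrame with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``, ``vclass`` ("SNP" or "InDel") and index = variant id.
    dosage : int8 array, shape (n_accessions, n_variants), values in
        {0, 1, 2, -1} with -1 = missing.
    """

    accession_ids: list
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.accession_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.variants)} variants"
            )
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- derived per-variant summaries -------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """ALT-allele frequency per variant over called allele copies."""
        called = self.dosage != MISSING
        copies = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(called, self.dosage, 0).sum(axis=0) / copies
        return freq

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def accession_index(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"accession {exc.args[0]!r} not in genotype matrix") from None

    def subset_variants(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            variants=self.variants.iloc[keep].copy(),
            dosage=self.dosage[:, keep].copy(),
        )

    def subset_accessions(self, ids) -> "GenotypeMatrix":
        idx = self.accession_index(ids)
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in idx],
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :].copy(),
        )

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of variants inside [start, end] (1-based inclusive)."""
        v = self.variants
        return ((v["chrom"] == chrom) & (v["pos"] >= start) & (v["pos"] <= end)).to_numpy()


@dataclass
class PhenotypeTable:
    """One row per accession: trait values plus group labels."""

    table: pd.DataFrame  # index = accession_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate accession ids in phenotype table")

    @property
    def accession_ids(self) -> list:
        return list(self.table.index)

    def trait(self, name: str, accessions=None) -> np.ndarray:
        t = self.table[name]
        if accessions is not None:
            t = t.loc[list(accessions)]
        return t.to_numpy(dtype=float)

    def labels(self, column: str, accessions=None) -> np.ndarray:
        c = self.table[column]
        if accessions is not None:
            c = c.loc[list(accessions)]
        return c.to_numpy()


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str           # "+" or "-"
    start: int            # 1-based inclusive gene span
    end: int
    cds: list             # list of (start, end) 1-based inclusive, sorted by position

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = None
        for s, e in self.cds:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"CDS segment ({s},{e}) outside gene span of {self.gene_id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
            prev_end = e

    def promoter(self, chrom_length: int | None = None) -> tuple:
        """2000-bp window upstream of the strand-aware TSS, clipped to the chromosome."""
        if self.strand == "+":
            lo, hi = self.start - PROMOTER_BP, self.start - 1
        else:
            lo, hi = self.end + 1, self.end + PROMOTER_BP
        lo = max(lo, 1)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return lo, hi

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneModelSet:
    genes: dict = field(default_factory=dict)  # gene_id -> Gene
    chrom_lengths: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def add(self, gene: Gene) -> None:
        self.genes[gene.gene_id] = gene

    def genes_on(self, chrom: str) -> list:
        return [g for g in self if g.chrom == chrom]

    def genes_in_region(self, chrom: str, start: int, end: int) -> list:
        return [g for g in self.genes_on(chrom) if g.start <= end and g.end >= start]


@dataclass
class ExpressionMatrix:
    """Gene x sample RPKM values with per-sample metadata.

    ``samples`` columns: variety, tissue ("root"/"shoot"), group
    ("robust"/"control"), replicate.
    """

    rpkm: pd.DataFrame        # index = gene_id, columns = sample ids
    samples: pd.DataFrame     # index = sample id

    def __post_init__(self) -> None:
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("negative RPKM")
        missing = set(self.rpkm.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("tissue", "group"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    def sample_ids(self, tissue: str | None = None, group: str | None = None) -> list:
        sel = pd.Series(True, index=self.samples.index)
        if tissue is not None:
            sel &= self.samples["tissue"] == tissue
        if group is not None:
            sel &= self.samples["group"] == group
        return [s for s in self.samples.index[sel] if s in self.rpkm.columns]


@dataclass
class LinkageQTLTable:
    """Bi-parental linkage-mapping QTL intervals used as external evidence."""

    table: pd.DataFrame  # columns: chrom, start, end, trait, parent1, parent2

    def __post_init__(self) -> None:
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("linkage interval with start > end")

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait]


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def qc_filter(g: GenotypeMatrix, max_missing: float = 0.5, min_maf: float = 0.05) -> GenotypeMatrix:
    """Retain variants with missing rate <= max_missing and MAF >= min_maf.

    Mirrors the panel QC of keeping un-imputed SNPs with missing rates <= 50%
    and minor allele frequencies >= 5%. Order is preserved; idempotent.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    keep = (g.missing_rate() <= max_missing) & (g.maf() >= min_maf)
    out = g.subset_variants(keep)
    logger.info("qc_filter: %d -> %d variants", g.n_variants, out.n_variants)
    return out


def ld_prune(g: GenotypeMatrix, r2_max: float = 0.3, window_bp: int = 170_000) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning.

    Scanning in genome order, a variant is dropped when its squared dosage
    correlation with any already-retained variant within ``window_bp``
    exceeds ``r2_max``. Zero-variance variants have r² treated as 0.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    dos = g.dosage.astype(float)
    dos[g.dosage == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(dos), col_mean[None, :], dos)
    centered = filled - filled.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))

    chroms = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    kept: list[int] = []
    kept_by_chrom: dict = {}
    for j in range(g.n_variants):
        drop = False
        for i in reversed(kept_by_chrom.get(chroms[j], [])):
            if pos[j] - pos[i] > window_bp:
                break
            if norms[i] == 0 or norms[j] == 0:
                continue  # zero-variance: r2 := 0
            r = centered[:, i] @ centered[:, j] / (norms[i] * norms[j])
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
            kept_by_chrom.setdefault(chroms[j], []).append(j)
    out = g.subset_variants(np.array(kept, dtype=int))
    logger.info("ld_prune: %d -> %d variants", g.n_variants, out.n_variants)
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF v4.2 into a GenotypeMatrix.

    Biallelic records only (multiallelic records are skipped with a log
    entry). Dosage = ALT-allele count; half-calls and ``./.`` are missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    accessions = list(vcf.samples)
    rows = []
    ids = []
    dosages = []
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1:
            logger.info("read_vcf: skipping multiallelic record %s:%d", rec.CHROM, rec.POS)
            continue
        ref, alt = rec.REF, rec.ALT[0]
        vclass = "SNP" if len(ref) == 1 and len(alt) == 1 else "InDel"
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        gts = rec.genotype.array()  # (n, ploidy+1); -1 = missing allele
        alleles = gts[:, :2]
        dose = np.where((alleles < 0).any(axis=1), MISSING, alleles.clip(min=0).sum(axis=1))
        rows.append((rec.CHROM, rec.POS, ref, alt, vclass))
        ids.append(vid)
        dosages.append(dose.astype(np.int8))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass"], index=ids)
    dosage = (
        np.array(dosages, dtype=np.int8).T
        if dosages
        else np.zeros((len(accessions), 0), dtype=np.int8)
    )
    return GenotypeMatrix(accession_ids=accessions, variants=variants, dosage=dosage)


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT fields, one sample per accession."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.accession_ids))
            + "\n"
        )
        vt = g.variants
        for j, (vid, row) in enumerate(vt.iterrows()):
            gts = "\t".join(_GT_CODE[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: GeneModelSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in genes.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in sorted(genes, key=lambda g: (g.chrom, g.start)):
            gid = gene.gene_id
            fh.write(
                f"{gene.chrom}\trootqtl\tgene\t{gene.start}\t{gene.end}\t.\t{gene.strand}\t.\t"
                f"ID={gid}\n"
            )
            fh.write(
                f"{gene.chrom}\trootqtl\tmRNA\t{gene.start}\t{gene.end}\t.\t{gene.strand}\t.\t"
                f"ID={gid}.1;Parent={gid}\n"
            )
            for s, e in gene.cds:
                fh.write(
                    f"{gene.chrom}\trootqtl\tCDS\t{s}\t{e}\t.\t{gene.strand}\t0\t"
                    f"ID={gid}.1.cds;Parent={gid}.1\n"
                )


def read_gff3(path) -> GeneModelSet:
    """Parse gene/mRNA/CDS features of a GFF3 file into a GeneModelSet."""
    out = GeneModelSet()
    gene_rows: dict = {}
    cds_rows: dict = {}
    mrna_parent: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                out.chrom_lengths[chrom] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gene_rows[attr["ID"]] = (chrom, strand, int(start), int(end))
            elif ftype == "mRNA":
                mrna_parent[attr["ID"]] = attr["Parent"]
            elif ftype == "CDS":
                gene_id = mrna_parent.get(attr.get("Parent", ""), attr.get("Parent", ""))
                cds_rows.setdefault(gene_id, []).append((int(start), int(end)))
    for gid, (chrom, strand, start, end) in gene_rows.items():
        cds = sorted(cds_rows.get(gid, []))
        out.add(Gene(gene_id=gid, chrom=chrom, strand=strand, start=start, end=end, cds=cds))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_phenotypes(p: PhenotypeTable, path) -> None:
    p.table.to_csv(path, sep="\t", index_label="accession")


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", index_col="accession"))


def write_expression(e: ExpressionMatrix, path_rpkm, path_samples) -> None:
    e.rpkm.to_csv(path_rpkm, sep="\t", index_label="gene_id")
    e.samples.to_csv(path_samples, sep="\t", index_label="sample")


def read_expression(path_rpkm, path_samples) -> ExpressionMatrix:
    return ExpressionMatrix(
        rpkm=pd.read_csv(path_rpkm, sep="\t", index_col="gene_id"),
        samples=pd.read_csv(path_samples, sep="\t", index_col="sample"),
    )


def write_linkage_qtls(t: LinkageQTLTable, path) -> None:
    t.table.to_csv(path, sep="\t", index=False)


def read_linkage_qtls(path, zero_based: bool = False) -> LinkageQTLTable:
    """Read a linkage-QTL TSV; set ``zero_based`` for BED-style half-open input."""
    tab = pd.read_csv(path, sep="\t")
    if zero_based:
        tab = tab.assign(start=tab["start"] + 1)
    return LinkageQTLTable(tab)
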