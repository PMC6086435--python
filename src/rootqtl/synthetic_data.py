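"""Synthetic two-subpopulation rice-like panels with planted root-trait QTLs.

The generator emulates the sampling structure the downstream pipeline is
built for: an inbred cultivated panel split into an *indica*-like and a
*japonica*-like subpopulation, an "upland" sub-branch of the *japonica*-like
group enriched (pyramided) for trait-increasing alleles, and a wild outgroup
drawn from a higher-diversity ancestral pool that carries nearly all alleles
segregating in the cultivated panel.

Genotypes are built from LD blocks: each block carries a small pool of
ancestral haplotypes, each accession draws one block haplotype according to
group-specific frequencies, and the dosage is twice the haplotype allele
(inbred coding, with a small residual heterozygosity rate). Causal genes sit
inside designated blocks where the haplotype pool is split into
"trait-increasing" and "other" haplotypes:

* variants inside the causal gene's ORF or 2000-bp promoter follow the split
  exactly (complete LD with the causal variant),
* intergenic block-mates follow it with a per-haplotype flip noise (tag
  SNPs, giving the clustered-significance signal the QTL caller needs),
* variants inside *other* genes' ORFs/promoters are balanced across the
  split, so decoy genes in the same block do not inherit coding-level
  association.

The phenotype is the sum of per-allele causal effects, a subpopulation
shift, and Gaussian noise scaled so the genetic fraction of phenotypic
variance matches ``trait_h2``. A single :class:`numpy.random.Generator`
seeded from ``config.seed`` drives all randomness; the stream order is
reference sequence, gene placement, variant placement, haplotype pools,
haplotype draws, heterozygosity/missingness masks, phenotype noise,
expression noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    Gene,
    GeneModelSet,
    GenotypeMatrix,
    ExpressionMatrix,
    LinkageQTLTable,
    PhenotypeTable,
    MISSING,
    write_expression,
    write_fasta,
    write_gff3,
    write_linkage_qtls,
    write_phenotypes,
    write_vcf,
)

TRAIT = "RL"  # root length, the panel's primary trait

# ancestral-pool geometry
N_POOL_HAPLOTYPES = 8
N_SUBPOP_HAPLOTYPES = 4
N_INCREASING_HAPLOTYPES = 3

# causal-allele frequency targets per group (trait-increasing allele)
CAUSAL_FREQ_WILD = 0.25
CAUSAL_FREQ_LOWLAND = 0.45
SWEEP_CONCENTRATION = 0.9  # share of upland increasing mass on the swept haplotype

GENE_SPAN_BP = 4000
GENE_SPACING_BP = 25_000
TAG_FLIP_RATE = 0.1       # per-haplotype noise on intergenic tag variants
DIFFERENTIAL_RATIO = 2.0  # robust/control RPKM ratio planted at causal genes


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation parameters."""


@dataclass
class SimulationConfig:
    n_accessions_per_subpop: int = 300
    n_wild: int = 60
    n_chromosomes: int = 3
    chrom_length_bp: int = 2_000_000
    n_variants: int = 3000
    ld_block_bp: int = 40_000
    n_causal_genes: int = 5
    causal_effect_sd: float = 0.5
    trait_h2: float = 0.5
    structure_shift_sd: float = 0.5
    upland_pyramiding_boost: float = 0.2
    structure_diff_fraction: float = 0.3
    maf_range: tuple = (0.1, 0.5)
    missing_rate: float = 0.02
    residual_het_rate: float = 0.005
    indel_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_accessions_per_subpop": self.n_accessions_per_subpop,
            "n_wild": self.n_wild,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_variants": self.n_variants,
            "ld_block_bp": self.ld_block_bp,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        fractions = {
            "trait_h2": self.trait_h2,
            "missing_rate": self.missing_rate,
            "residual_het_rate": self.residual_het_rate,
            "indel_fraction": self.indel_fraction,
            "structure_diff_fraction": self.structure_diff_fraction,
        }
        for name, value in fractions.items():
            if not 0 <= value <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if not 0 <= self.upland_pyramiding_boost <= 0.5:
            raise ConfigError("upland_pyramiding_boost must lie in [0, 0.5]")
        lo, hi = self.maf_range
        if not (0 <= lo < hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 <= low < high <= 0.5, got {self.maf_range}")
        if self.n_causal_genes < 0:
            raise ConfigError("n_causal_genes must be >= 0")
        if self.n_variants // self.n_chromosomes < 10:
            raise ConfigError("need at least 10 variants per chromosome")


@dataclass
class PlantedTruth:
    causal_gene_ids: list
    causal_variant_ids: list
    increasing_allele: dict      # variant id -> "ref"/"alt"
    effect_size: dict            # variant id -> trait units per allele copy
    groups: pd.DataFrame = field(default=None)  # index accession: subpop, ecotype


@dataclass
class SyntheticPanel:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    genes: GeneModelSet
    reference: dict
    expression: ExpressionMatrix
    linkage_qtls: LinkageQTLTable
    truth: PlantedTruth

    def write(self, outdir) -> None:
        """Serialize every component to the standard text formats."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(self.genotypes, outdir / "panel.vcf")
        write_phenotypes(self.phenotypes, outdir / "phenotypes.tsv")
        write_gff3(self.genes, outdir / "genes.gff3")
        write_fasta(self.reference, outdir / "reference.fa")
        write_expression(self.expression, outdir / "rpkm.tsv", outdir / "rpkm_samples.tsv")
        write_linkage_qtls(self.linkage_qtls, outdir / "linkage_qtls.tsv")
        truth = pd.DataFrame(
            {
                "variant": self.truth.causal_variant_ids,
                "gene": self.truth.causal_gene_ids,
                "increasing_allele": [
                    self.truth.increasing_allele[v] for v in self.truth.causal_variant_ids
                ],
                "effect": [self.truth.effect_size[v] for v in self.truth.causal_variant_ids],
            }
        )
        truth.to_csv(outdir / "planted_truth.tsv", sep="\t", index=False)
        self.truth.groups.to_csv(outdir / "groups.tsv", sep="\t", index_label="accession")


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _random_reference(rng, chroms: list, length: int) -> dict:
    return {c: "".join(_BASES[rng.integers(0, 4, size=length)]) for c in chroms}


def _orf_codons(rng, n_codons: int) -> str:
    """A start codon, internal codons free of stops, and a stop codon."""
    internal = []
    while len(internal) < n_codons - 2:
        codon = "".join(_BASES[rng.integers(0, 4, size=3)])
        if codon not in _STOPS:
            internal.append(codon)
    return "ATG" + "".join(internal) + "TAA"


_COMP = str.maketrans("ACGT", "TGCA")


def _place_genes(rng, chroms: list, chrom_length: int) -> GeneModelSet:
    genes = GeneModelSet(chrom_lengths={c: chrom_length for c in chroms})
    for c_idx, chrom in enumerate(chroms):
        start = 10_000
        g = 0
        while start + GENE_SPAN_BP < chrom_length - 10_000:
            gid = f"gene{c_idx + 1:02d}g{g + 1:03d}"
            strand = "+" if g % 2 == 0 else "-"
            end = start + GENE_SPAN_BP - 1
            # two CDS segments separated by an intron, lengths multiple of 3
            cds1 = (start + 200, start + 200 + 899)
            cds2 = (start + 1600, start + 1600 + 1199)
            genes.add(Gene(gene_id=gid, chrom=chrom, strand=strand, start=start, end=end, cds=[cds1, cds2]))
            start += GENE_SPACING_BP
            g += 1
    return genes


def _install_orfs(rng, reference: dict, genes: GeneModelSet) -> None:
    """Overwrite each gene's CDS in the reference with a clean ORF."""
    buffers = {c: list(seq) for c, seq in reference.items()}
    for gene in genes:
        n_codons = gene.cds_length() // 3
        orf = _orf_codons(rng, n_codons)
        if gene.strand == "-":
            orf = orf[::-1].translate(_COMP)  # genomic = revcomp of coding
            # on the minus strand the coding order runs last CDS segment first,
            # so genomic concatenation of segments equals revcomp(coding)
        k = 0
        for s, e in gene.cds:
            seg_len = e - s + 1
            buffers[gene.chrom][s - 1 : e] = orf[k : k + seg_len]
            k += seg_len
    for c in reference:
        reference[c] = "".join(buffers[c])


def _gene_zone_masks(genes_on_chrom, positions, chrom_length):
    """Per-variant gene hit: returns arrays (gene index or -1) for ORF/promoter zones."""
    in_gene_zone = np.full(positions.shape, -1, dtype=int)
    for gi, gene in enumerate(genes_on_chrom):
        plo, phi = gene.promoter(chrom_length)
        hit = ((positions >= gene.start) & (positions <= gene.end)) | (
            (positions >= plo) & (positions <= phi)
        )
        in_gene_zone[hit] = gi
    return in_gene_zone


def _aa_changing_alt(gene, vpos: int, ref: str, reference: dict) -> str | None:
    """First alternate base (A<C<G<T) whose substitution changes the protein,
    or None when the site is 4-fold degenerate."""
    from Bio.Seq import Seq

    from .candidate_screen import _coding_index, _coding_sequence

    cds_seq = _coding_sequence(gene, reference)
    idx = _coding_index(gene, vpos)
    if idx is None:
        return None
    codon_i, within = idx // 3, idx % 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    aa_old = str(Seq(codon).translate())
    for alt in "ACGT":
        if alt == ref:
            continue
        nb = alt if gene.strand == "+" else alt.translate(_COMP)
        new_codon = codon[:within] + nb + codon[within + 1 :]
        if str(Seq(new_codon).translate()) != aa_old:
            return alt
    return None


def simulate_panel(config: SimulationConfig) -> SyntheticPanel:
    """Generate a full panel with planted truth. See the module docstring."""
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    L = config.chrom_length_bp

    # 1. reference and gene models
    reference = _random_reference(rng, chroms, L)
    genes = _place_genes(rng, chroms, L)
    _install_orfs(rng, reference, genes)

    # 2. variant placement
    per_chrom = np.full(config.n_chromosomes, config.n_variants // config.n_chromosomes)
    per_chrom[: config.n_variants % config.n_chromosomes] += 1
    variant_rows = []
    variant_ids = []
    chrom_pos: dict = {}
    for chrom, n_v in zip(chroms, per_chrom):
        pos = np.sort(rng.choice(np.arange(1000, L - 1000), size=n_v, replace=False))
        chrom_pos[chrom] = pos
        is_indel = rng.random(n_v) < config.indel_fraction
        seq = reference[chrom]
        for p, ind in zip(pos, is_indel):
            ref_base = seq[p - 1]
            if ind:
                ref = seq[p - 1 : p + 1]
                alt = ref_base  # 1-bp deletion
                vclass = "InDel"
            else:
                ref = ref_base
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                vclass = "SNP"
            variant_rows.append((chrom, int(p), ref, alt, vclass))
            variant_ids.append(f"{chrom}_{p}")
    variants = pd.DataFrame(
        variant_rows, columns=["chrom", "pos", "ref", "alt", "vclass"], index=variant_ids
    )
    m = len(variants)

    # 3. accession bookkeeping
    n_sub = config.n_accessions_per_subpop
    acc_ids = (
        [f"IND{i + 1:04d}" for i in range(n_sub)]
        + [f"JAP{i + 1:04d}" for i in range(n_sub)]
        + [f"WILD{i + 1:04d}" for i in range(config.n_wild)]
    )
    n_acc = len(acc_ids)
    subpop = np.array(["indica"] * n_sub + ["japonica"] * n_sub + ["wild"] * config.n_wild)
    # upland sub-branch: second half of the japonica-like group
    ecotype = np.array(["lowland"] * n_acc, dtype=object)
    ecotype[subpop == "wild"] = "wild"
    jap_idx = np.flatnonzero(subpop == "japonica")
    ecotype[jap_idx[len(jap_idx) // 2 :]] = "upland"
    groups = pd.DataFrame({"subpop": subpop, "ecotype": ecotype}, index=acc_ids)

    # 4. choose causal genes: spread over chromosomes, must contain ORF/promoter variants
    zone_by_chrom = {
        c: _gene_zone_masks(genes.genes_on(c), chrom_pos[c], L) for c in chroms
    }
    eligible = []
    for chrom in chroms:
        glist = genes.genes_on(chrom)
        for gi, gene in enumerate(glist):
            hits = np.flatnonzero(zone_by_chrom[chrom] == gi)
            orf_hits = [
                k for k in hits if any(s <= chrom_pos[chrom][k] <= e for s, e in gene.cds)
            ]
            if hits.size:
                eligible.append((chrom, gi, gene, hits, orf_hits))
    if config.n_causal_genes > len(eligible):
        raise ConfigError(
            f"n_causal_genes={config.n_causal_genes} exceeds the {len(eligible)} genes "
            "containing variants in their ORF or promoter"
        )
    # prefer genes with coding variants (planted causal variants are coding
    # where possible), spread evenly through the genome
    with_orf = [e for e in eligible if e[4]]
    source = with_orf if len(with_orf) >= config.n_causal_genes else eligible
    if config.n_causal_genes:
        pick = np.linspace(0, len(source) - 1, config.n_causal_genes).round().astype(int)
        causal = [source[i] for i in sorted(set(pick))]
        while len(causal) < config.n_causal_genes:  # collision fallback
            extra = [e for e in source if e not in causal]
            causal.append(extra[0])
    else:
        causal = []

    # pick each causal gene's planted variant globally (ORF hit preferred),
    # independent of LD-block boundaries
    chrom_offset = {}
    off = 0
    for chrom, n_v in zip(chroms, per_chrom):
        chrom_offset[chrom] = off
        off += n_v
    causal_variant_col = {}
    for chrom_c, gi_c, gene_c, hits_c, orf_hits_c in causal:
        # prefer a coding site where some substitution changes the protein
        # (4-fold degenerate third positions admit none)
        chosen_k = None
        for k in orf_hits_c:
            vpos = int(chrom_pos[chrom_c][k])
            ref_b = reference[chrom_c][vpos - 1]
            if _aa_changing_alt(gene_c, vpos, ref_b, reference) is not None:
                chosen_k = k
                break
        if chosen_k is None:
            chosen_k = (orf_hits_c or list(hits_c))[0]
        causal_variant_col[gene_c.gene_id] = chrom_offset[chrom_c] + int(chosen_k)

    # 5. haplotype pools per LD block, with group-specific frequencies
    lo, hi = config.maf_range
    inc_set = np.arange(N_INCREASING_HAPLOTYPES)  # haplotype indices carrying the increasing allele
    f_up = min(CAUSAL_FREQ_LOWLAND + config.upland_pyramiding_boost, 0.95)

    dosage = np.zeros((n_acc, m), dtype=np.int8)
    truth_variant_ids: list = []
    truth_gene_ids: list = []
    causal_col: list = []

    group_code = np.zeros(n_acc, dtype=int)  # 0=indica, 1=japonica, 2=wild, 3=upland japonica
    group_code[subpop == "japonica"] = 1
    group_code[subpop == "wild"] = 2
    group_code[(subpop == "japonica") & (ecotype == "upland")] = 3

    col_offset = 0
    for chrom in chroms:
        pos = chrom_pos[chrom]
        n_v = len(pos)
        zone = zone_by_chrom[chrom]
        glist = genes.genes_on(chrom)
        causal_here = {gi: (gene, hits, orf_hits) for (c, gi, gene, hits, orf_hits) in causal if c == chrom}
        block_id = pos // config.ld_block_bp
        for b in np.unique(block_id):
            cols = np.flatnonzero(block_id == b)
            mb = cols.size
            # ancestral pool alleles
            p_anc = rng.uniform(lo, hi, size=mb)
            flip = rng.random(mb) < 0.5
            p_anc = np.where(flip, 1.0 - p_anc, p_anc)
            H = (rng.random((N_POOL_HAPLOTYPES, mb)) < p_anc[None, :]).astype(np.int8)

            causal_gis = [gi for gi in causal_here if np.any(zone[cols] == gi)]
            is_causal_block = bool(causal_gis)

            if is_causal_block:
                gi = causal_gis[0]
                gene, hits, orf_hits = causal_here[gi]
                inc_mask = np.isin(np.arange(N_POOL_HAPLOTYPES), inc_set)
                sweep_mask = np.arange(N_POOL_HAPLOTYPES) == inc_set[0]
                local_zone = zone[cols]
                causal_local = None
                own_zone_ordinal = 0
                for k_local in range(mb):
                    gidx = local_zone[k_local]
                    if gidx == gi:
                        vcol_here = col_offset + cols[k_local]
                        if vcol_here == causal_variant_col.get(gene.gene_id):
                            # the planted variant itself: perfect trait split
                            H[:, k_local] = inc_mask.astype(np.int8)
                            causal_local = k_local
                        elif own_zone_ordinal % 2 == 0:
                            # half the gene's variants tag the trait split ...
                            H[:, k_local] = inc_mask.astype(np.int8)
                            own_zone_ordinal += 1
                        else:
                            # ... the rest tag the swept founder haplotype,
                            # so the sweep is visible inside the gene span
                            H[:, k_local] = sweep_mask.astype(np.int8)
                            own_zone_ordinal += 1
                    elif gidx >= 0:
                        # decoy gene's ORF/promoter: balanced across the split
                        alleles = np.zeros(N_POOL_HAPLOTYPES, dtype=np.int8)
                        inc_half = rng.permutation(inc_set)[: len(inc_set) // 2 + 1]
                        other = np.setdiff1d(np.arange(N_POOL_HAPLOTYPES), inc_set)
                        oth_half = rng.permutation(other)[: len(other) // 2 + 1]
                        alleles[inc_half] = 1
                        alleles[oth_half] = 1
                        H[:, k_local] = alleles
                    else:
                        # intergenic: tag variant with flip noise, or untouched
                        if rng.random() < 0.5:
                            tag = inc_mask.astype(np.int8)
                            flips = rng.random(N_POOL_HAPLOTYPES) < TAG_FLIP_RATE
                            H[:, k_local] = np.where(flips, 1 - tag, tag)
                # group haplotype frequencies hit the causal-allele targets
                def split_freq(f_inc, swept=False, lowland=False):
                    w = np.empty(N_POOL_HAPLOTYPES)
                    others = np.setdiff1d(np.arange(N_POOL_HAPLOTYPES), inc_set)
                    if swept:
                        # upland selective sweep: most of the increasing mass
                        # rides one founder haplotype, leaving the hallmark
                        # diversity reduction at the locus
                        w[inc_set] = f_inc * (1.0 - SWEEP_CONCENTRATION) / max(len(inc_set) - 1, 1)
                        w[inc_set[0]] = f_inc * SWEEP_CONCENTRATION
                    elif lowland:
                        # the swept founder haplotype is upland-specific;
                        # lowland groups carry the other increasing haplotypes
                        w[inc_set] = f_inc / max(len(inc_set) - 1, 1)
                        w[inc_set[0]] = 0.0
                    else:
                        w[inc_set] = f_inc / len(inc_set)
                    w[others] = (1.0 - f_inc) / len(others)
                    return w
                freqs = np.vstack(
                    [
                        split_freq(CAUSAL_FREQ_LOWLAND, lowland=True),  # indica
                        split_freq(CAUSAL_FREQ_LOWLAND, lowland=True),  # lowland japonica
                        split_freq(CAUSAL_FREQ_WILD),                   # wild: ancestral pool
                        split_freq(f_up, swept=True),                   # upland japonica
                    ]
                )
                if gene.gene_id not in truth_gene_ids:  # gene may span two blocks
                    vcol = causal_variant_col[gene.gene_id]
                    truth_variant_ids.append(variants.index[vcol])
                    truth_gene_ids.append(gene.gene_id)
                    causal_col.append(vcol)
            else:
                # neutral block: subpops draw from partially overlapping subsets
                differentiated = rng.random() < config.structure_diff_fraction
                if differentiated:
                    sets = [np.arange(0, N_SUBPOP_HAPLOTYPES), np.arange(N_POOL_HAPLOTYPES - N_SUBPOP_HAPLOTYPES, N_POOL_HAPLOTYPES)]
                else:
                    shared = rng.permutation(N_POOL_HAPLOTYPES)[:N_SUBPOP_HAPLOTYPES]
                    sets = [shared, shared]
                freqs = np.zeros((4, N_POOL_HAPLOTYPES))
                for s_idx, hap_set in enumerate(sets):
                    w = rng.dirichlet(np.ones(len(hap_set)) * 2.0)
                    freqs[s_idx, hap_set] = w
                freqs[3] = freqs[1]                      # upland shares lowland japonica structure
                freqs[2] = np.full(N_POOL_HAPLOTYPES, 1.0 / N_POOL_HAPLOTYPES)  # wild: full pool

            cum = np.cumsum(freqs, axis=1)
            u = rng.random(n_acc)
            hap_idx = (u[:, None] > cum[group_code]).sum(axis=1)
            dosage[:, col_offset + cols] = 2 * H[hap_idx, :]
        col_offset += n_v

    # 6. residual heterozygosity and missingness
    het = rng.random(dosage.shape) < config.residual_het_rate
    dosage[het] = 1
    clean_dosage = dosage.copy()
    miss = rng.random(dosage.shape) < config.missing_rate
    dosage[miss] = MISSING

    # 7. phenotype (trait_h2 = 0 plants no genetic signal: effects are zero)
    planted_effect = 0.0 if config.trait_h2 == 0 else config.causal_effect_sd
    effect = {v: planted_effect for v in truth_variant_ids}
    genetic = clean_dosage[:, causal_col].astype(float) @ np.full(len(causal_col), config.causal_effect_sd)
    shift = np.where(subpop == "japonica", config.structure_shift_sd, 0.0)
    cultivated = subpop != "wild"
    y = np.full(n_acc, np.nan)
    if config.trait_h2 == 0 or not causal_col:
        noise = rng.normal(0.0, 1.0, size=n_acc)
        y[cultivated] = (shift + noise)[cultivated]
    else:
        var_g = float(np.var(genetic[cultivated]))
        var_gs = float(np.var((genetic + shift)[cultivated]))
        var_e = var_g / config.trait_h2 - var_gs
        if var_e <= 0:
            raise ConfigError(
                f"trait_h2={config.trait_h2} infeasible: structure variance already "
                "exceeds the non-genetic budget"
            )
        noise = rng.normal(0.0, np.sqrt(var_e), size=n_acc)
        y[cultivated] = (genetic + shift + noise)[cultivated]

    pheno = PhenotypeTable(
        pd.DataFrame({TRAIT: y, "subpop": subpop, "ecotype": ecotype}, index=acc_ids)
    )

    # 8. expression matrix: 6 robust + 6 control varieties, root and shoot, 2 reps
    causal_set = set(truth_gene_ids)
    gene_ids = [g.gene_id for g in genes]
    sample_meta = []
    sample_ids = []
    for grp, n_var in (("robust", 6), ("control", 6)):
        for v in range(n_var):
            for tissue in ("root", "shoot"):
                for rep in (1, 2):
                    sid = f"{grp}{v + 1}_{tissue}_r{rep}"
                    sample_ids.append(sid)
                    sample_meta.append((f"{grp.upper()}{v + 1}", tissue, grp, rep))
    samples = pd.DataFrame(
        sample_meta, columns=["variety", "tissue", "group", "replicate"], index=sample_ids
    )
    base = rng.lognormal(mean=1.0, sigma=0.8, size=len(gene_ids))
    rpkm = np.zeros((len(gene_ids), len(sample_ids)))
    for gi, gid in enumerate(gene_ids):
        root_specific = gid in causal_set and (sorted(causal_set).index(gid) % 3 == 2)
        for si, sid in enumerate(sample_ids):
            tissue = samples.iloc[si]["tissue"]
            grp = samples.iloc[si]["group"]
            mean = base[gi]
            if gid in causal_set:
                if root_specific:
                    mean = 5.0 if tissue == "root" else 0.05
                    if tissue == "root" and grp == "robust":
                        mean *= DIFFERENTIAL_RATIO
                elif tissue == "root" and grp == "robust":
                    mean *= DIFFERENTIAL_RATIO
            rpkm[gi, si] = mean * rng.lognormal(mean=0.0, sigma=0.15)
    expression = ExpressionMatrix(
        rpkm=pd.DataFrame(rpkm, index=gene_ids, columns=sample_ids), samples=samples
    )

    # 9. linkage-mapping QTL intervals for ~60% of causal genes, plus decoys
    link_rows = []
    n_link = max(1, int(round(0.6 * len(truth_gene_ids)))) if truth_gene_ids else 0
    for gid, vid in list(zip(truth_gene_ids, truth_variant_ids))[:n_link]:
        gene = genes[gid]
        vcol = variants.index.get_loc(vid)
        d = clean_dosage[:, vcol]
        hi_acc = [acc_ids[i] for i in np.flatnonzero((d == 2) & cultivated)]
        lo_acc = [acc_ids[i] for i in np.flatnonzero((d == 0) & cultivated)]
        if not hi_acc or not lo_acc:
            continue
        link_rows.append(
            (
                gene.chrom,
                max(1, gene.start - 50_000),
                min(L, gene.end + 50_000),
                TRAIT,
                hi_acc[0],
                lo_acc[0],
            )
        )
    # decoy intervals far from any causal gene
    for chrom in chroms[: max(1, len(chroms) // 2)]:
        link_rows.append((chrom, L - 300_000, L - 100_000, TRAIT, acc_ids[0], acc_ids[1]))
    linkage = LinkageQTLTable(
        pd.DataFrame(link_rows, columns=["chrom", "start", "end", "trait", "parent1", "parent2"])
    )

    # planted causal coding variants are amino-acid-changing by construction:
    # a causal ORF allele that leaves the protein untouched would contradict
    # the planted functional role
    for t_idx, (vid, gid) in enumerate(zip(truth_variant_ids, truth_gene_ids)):
        gene = genes[gid]
        row = variants.loc[vid]
        vpos = int(row["pos"])
        if row["vclass"] != "SNP" or not any(s <= vpos <= e for s, e in gene.cds):
            continue
        alt = _aa_changing_alt(gene, vpos, row["ref"], reference)
        if alt is not None:
            variants.loc[vid, "alt"] = alt
            continue
        # 4-fold degenerate site: nudge the variant inside its codon to a
        # position where protein-changing substitutions exist
        for newpos in (vpos - 1, vpos + 1, vpos - 2, vpos + 2):
            new_id = f"{gene.chrom}_{newpos}"
            between = range(min(vpos, newpos), max(vpos, newpos) + 1)
            if any(f"{gene.chrom}_{q}" in variants.index for q in between if q != vpos):
                continue  # keep positions strictly increasing
            if not any(s <= newpos <= e for s, e in gene.cds):
                continue
            new_ref = reference[gene.chrom][newpos - 1]
            alt = _aa_changing_alt(gene, newpos, new_ref, reference)
            if alt is None:
                continue
            variants.loc[vid, ["pos", "ref", "alt"]] = [newpos, new_ref, alt]
            variants.rename(index={vid: new_id}, inplace=True)
            truth_variant_ids[t_idx] = new_id
            effect[new_id] = effect.pop(vid)
            break

    genotypes = GenotypeMatrix(accession_ids=acc_ids, variants=variants, dosage=dosage)
    truth = PlantedTruth(
        causal_gene_ids=truth_gene_ids,
        causal_variant_ids=truth_variant_ids,
        increasing_allele={v: "alt" for v in truth_variant_ids},
        effect_size=effect,
        groups=groups,
    )
    return SyntheticPanel(
        genotypes=genotypes,
        phenotypes=pheno,
        genes=genes,
        reference=reference,
        expression=expression,
        linkage_qtls=linkage,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# verification helper
# ---------------------------------------------------------------------------

def realized_h2(truth: PlantedTruth, genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                trait: str = TRAIT) -> float:
    """Fraction of phenotypic variance explained by the planted genetic values.

    Genetic value per accession = sum over causal variants of effect x dosage
    (missing dosages mean-imputed). Computed over accessions with a finite
    trait value; raises if fewer than two remain.
    """
    ids = [a for a in genotypes.accession_ids if a in phenotypes.table.index]
    if set(ids) != set(phenotypes.table.index):
        extra = set(phenotypes.table.index) - set(ids)
        raise ValueError(f"phenotyped accessions missing from genotypes: {sorted(extra)[:3]}")
    y = phenotypes.trait(trait, ids)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("need at least two phenotyped accessions to compute variance")
    rows = genotypes.accession_index(ids)
    cols = [genotypes.variants.index.get_loc(v) for v in truth.causal_variant_ids]
    if not cols:
        return 0.0
    d = genotypes.dosage[np.ix_(rows, cols)].astype(float)
    d[d == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean[None, :], d)
    betas = np.array([truth.effect_size[v] for v in truth.causal_variant_ids])
    g = d @ betas
    var_y = float(np.var(y[ok]))
    if var_y == 0:
        raise ValueError("phenotype has zero variance")
    return float(np.var(g[ok]) / var_y)
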