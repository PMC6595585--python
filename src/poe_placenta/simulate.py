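"""Synthetic trio/duo cohort generator with a ground-truth ledger.

The generator emulates the statistical structure the analysis assumes:
Hardy-Weinberg parental genotypes at a given minor allele frequency,
Mendelian transmission to the placenta, and per-SNP allele-specific read
counts in which each read is maternal-placental with probability
(1 - rho) * theta, paternal-placental with probability
(1 - rho) * (1 - theta), or a maternal-cell contaminant with probability
rho (default 0.93%, the published estimate for this tissue).  Contaminant
reads carry the mother's own alleles; every read finally flips allele with
the sequencing error probability epsilon.  Sequencing depth per SNP is
Poisson.

Duos are simulated by drawing and then hiding a father, so the truth
ledger can score duo informativeness rules.  Everything is driven by a
single integer-seeded generator: identical seeds give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from poe_placenta.config import Genotype, TrioFamily
from poe_placenta.io import (
    GenotypeTable,
    write_allelic_counts,
    write_exon_bed,
    write_gene_counts,
    write_genotypes_vcf,
    write_pedigree,
)

_ALLELE_LABEL = {0: "ref", 1: "alt"}


@dataclass
class GeneModel:
    """Ground-truth generative parameters of one gene.

    ``theta`` is the true maternal share of placental transcripts: 1 for a
    fully maternally expressed imprinted gene, 0.5 for biallelic.
    """

    gene_id: str
    theta: float
    n_snps: int = 2
    snp_mafs: Optional[List[float]] = None
    mean_depth: float = 50.0
    gene_length_bp: int = 2000
    mean_expression: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.n_snps < 1:
            raise ValueError("a gene needs at least one SNP")
        if self.snp_mafs is None:
            self.snp_mafs = [0.4] * self.n_snps
        if len(self.snp_mafs) != self.n_snps:
            raise ValueError("snp_mafs length must equal n_snps")
        for maf in self.snp_mafs:
            if not 0.0 < maf <= 0.5:
                raise ValueError("each MAF must lie in (0, 0.5]")


@dataclass(frozen=True)
class NoiseModel:
    """Maternal-cell contamination and per-read sequencing error."""

    contamination_rho: float = 0.0093
    seq_error_eps: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_rho < 0.5:
            raise ValueError("contamination fraction must lie in [0, 0.5)")
        if not 0.0 <= self.seq_error_eps < 0.5:
            raise ValueError("sequencing error rate must lie in [0, 0.5)")


@dataclass
class SimTruth:
    """Ground-truth ledger: per-gene theta/class and per-(family, SNP) phase."""

    genes: pd.DataFrame  # gene_id, theta, true_class
    phase: pd.DataFrame  # family_id, snp_id, maternal_allele, paternal_allele
    seed: int


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces, in memory."""

    families: List[TrioFamily]
    genotype_table: GenotypeTable
    snp_genes: pd.Series  # snp_id -> gene_id
    exons: pd.DataFrame
    allelic_counts: pd.DataFrame
    gene_counts: pd.DataFrame
    gene_lengths: pd.Series
    truth: SimTruth


def true_class(theta: float, imprinted_threshold: float = 0.90, biased_low: float = 0.65) -> str:
    """The classifier's decision rule applied to the true theta itself."""
    f = max(theta, 1.0 - theta)
    if f > imprinted_threshold:
        return "imprinted"
    if f >= biased_low:
        return "biased"
    return "biallelic"


# --------------------------------------------------------------------------
# primitive draws


def simulate_parent_genotypes(
    maf: float, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw unrelated genotypes at Hardy-Weinberg frequencies p^2, 2pq, q^2."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    q = maf
    p = 1.0 - q
    return rng.choice(
        np.array([0, 1, 2], dtype=np.int8),
        size=n_individuals,
        p=[p * p, 2 * p * q, q * q],
    )


def simulate_offspring(
    mother_gt: int, father_gt: int, rng: np.random.Generator
) -> Tuple[int, int, int]:
    """Mendelian transmission: one allele drawn uniformly from each parent.

    Returns (placental dosage, maternal allele, paternal allele) with
    alleles coded 0 = ref, 1 = alt.
    """
    if mother_gt == Genotype.MISSING or father_gt == Genotype.MISSING:
        raise ValueError("parental genotypes must be non-missing")
    maternal = _transmit(int(mother_gt), rng)
    paternal = _transmit(int(father_gt), rng)
    return maternal + paternal, maternal, paternal


def _transmit(gt: int, rng: np.random.Generator) -> int:
    if gt == 0:
        return 0
    if gt == 2:
        return 1
    return int(rng.integers(0, 2))


def simulate_allelic_reads(
    maternal_allele: int,
    paternal_allele: int,
    mother_gt: int,
    theta: float,
    depth_mean: float,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> Tuple[int, int]:
    """Draw one placental pileup at a SNP: (ref_reads, alt_reads).

    Reads are a three-way mixture of maternal-placental, paternal-placental
    and maternal-cell contaminant reads; contaminant reads carry one of the
    mother's two alleles (equiprobably if she is heterozygous); each read
    then flips allele with the sequencing error probability.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    rho = noise.contamination_rho
    depth = int(rng.poisson(depth_mean))
    if depth == 0:
        return 0, 0
    n_mat, n_pat, n_cont = rng.multinomial(
        depth, [(1.0 - rho) * theta, (1.0 - rho) * (1.0 - theta), rho]
    )
    if mother_gt == Genotype.HET:
        cont_alt = int(rng.binomial(n_cont, 0.5))
    else:
        cont_alt = n_cont if mother_gt == Genotype.HOM_ALT else 0
    alt = n_mat * maternal_allele + n_pat * paternal_allele + cont_alt
    ref = depth - alt
    eps = noise.seq_error_eps
    if eps > 0.0:
        alt_to_ref = int(rng.binomial(alt, eps))
        ref_to_alt = int(rng.binomial(ref, eps))
        alt = alt - alt_to_ref + ref_to_alt
        ref = depth - alt
    return int(ref), int(alt)


# --------------------------------------------------------------------------
# cohort layout

#: (clinical group, trios, duos) as in the reference cohort of 54
#: pregnancies: 38 mother-father-placenta trios and 16 mother-placenta duos.
TABLE1_LAYOUT: Tuple[Tuple[str, int, int], ...] = (
    ("trim1", 0, 8),
    ("trim2", 0, 6),
    ("trim3_normal", 8, 0),
    ("SGA", 7, 1),
    ("LGA", 7, 1),
    ("PE", 8, 0),
    ("GD", 8, 0),
)

#: observed gestational-age range (days) per clinical group
_GA_RANGE: Dict[str, Tuple[int, int]] = {
    "trim1": (51, 81),
    "trim2": (126, 167),
    "trim3_normal": (260, 291),
    "SGA": (264, 289),
    "LGA": (275, 288),
    "PE": (260, 271),
    "GD": (268, 284),
}


def default_table1_families(rng: Optional[np.random.Generator] = None) -> List[TrioFamily]:
    """The 54-family reference layout, with gestational ages drawn uniformly
    within each group's observed range."""
    if rng is None:
        rng = np.random.default_rng(0)
    families: List[TrioFamily] = []
    i = 0
    for group, n_trios, n_duos in TABLE1_LAYOUT:
        lo, hi = _GA_RANGE[group]
        for kind, count in (("trio", n_trios), ("duo", n_duos)):
            for _ in range(count):
                i += 1
                fid = f"F{i:03d}"
                families.append(
                    TrioFamily(
                        family_id=fid,
                        placenta_sample=f"{fid}_P",
                        mother_sample=f"{fid}_M",
                        father_sample=f"{fid}_F" if kind == "trio" else None,
                        clinical_group=group,
                        gestational_age_days=int(rng.integers(lo, hi + 1)),
                    )
                )
    return families


def default_gene_panel() -> List[GeneModel]:
    """A 25-gene panel mirroring the published class mix: 4 maternally and
    7 paternally imprinted, 4 maternally and 10 paternally biased genes.

    Default thetas bracket the observed range: 0.98/0.02 for imprinted,
    0.75/0.17 for biased genes.
    """
    panel: List[GeneModel] = []
    specs = [
        ("IMPM", 0.98, 4),
        ("IMPP", 0.02, 7),
        ("BIAM", 0.75, 4),
        ("BIAP", 0.17, 10),
    ]
    for prefix, theta, count in specs:
        for i in range(1, count + 1):
            panel.append(GeneModel(gene_id=f"{prefix}{i:02d}", theta=theta))
    return panel


def make_gene_models(
    thetas: Sequence[float], prefix: str = "G", **kwargs
) -> List[GeneModel]:
    """Convenience constructor: one GeneModel per theta, shared settings."""
    return [
        GeneModel(gene_id=f"{prefix}{i + 1:04d}", theta=float(t), **kwargs)
        for i, t in enumerate(thetas)
    ]


# --------------------------------------------------------------------------
# whole-cohort generation


def generate_cohort(
    families: Optional[Sequence[TrioFamily]] = None,
    genes: Optional[Sequence[GeneModel]] = None,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
) -> CohortBundle:
    """Simulate genotypes, allelic read counts, a gene count matrix and the
    ground-truth ledger for a whole cohort.

    Every placental sample gets a pileup record at every SNP, informative
    or not, mirroring real tabulated pileup output.
    """
    rng = np.random.default_rng(seed)
    if families is None:
        families = default_table1_families(rng)
    families = list(families)
    if genes is None:
        genes = default_gene_panel()
    genes = list(genes)
    if not families:
        raise ValueError("cohort needs at least one family")
    if not genes:
        raise ValueError("cohort needs at least one gene")
    if noise is None:
        noise = NoiseModel()

    # genomic layout: genes laid out end to end on chr1, one exon per gene
    snp_rows = []
    exon_rows = []
    snp_genes: Dict[str, str] = {}
    offset = 0
    for gene in genes:
        start = offset  # 0-based
        end = start + gene.gene_length_bp
        exon_rows.append(
            {"chrom": "chr1", "start": start, "end": end, "gene_id": gene.gene_id}
        )
        for j in range(gene.n_snps):
            pos = start + 1 + (j + 1) * gene.gene_length_bp // (gene.n_snps + 1)
            snp_id = f"{gene.gene_id}_snp{j + 1}"
            snp_rows.append(
                {
                    "snp_id": snp_id,
                    "chrom": "chr1",
                    "pos": pos,
                    "ref_allele": "A",
                    "alt_allele": "G",
                }
            )
            snp_genes[snp_id] = gene.gene_id
        offset = end + 1000
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "ref_allele", "alt_allele"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene_id"])

    samples: List[str] = []
    for f in families:
        samples.append(f.placenta_sample)
        samples.append(f.mother_sample)
        if f.father_sample is not None:
            samples.append(f.father_sample)
    genotypes = pd.DataFrame(
        np.zeros((len(samples), len(snps)), dtype=np.int8),
        index=pd.Index(samples, name="sample"),
        columns=snps["snp_id"].tolist(),
    )

    phase_rows = []
    count_rows = []
    snp_index = 0
    for gene in genes:
        for j, maf in enumerate(gene.snp_mafs):
            snp_id = snps["snp_id"].iloc[snp_index]
            snp_index += 1
            mothers = simulate_parent_genotypes(maf, len(families), rng)
            fathers = simulate_parent_genotypes(maf, len(families), rng)
            for k, fam in enumerate(families):
                m_gt, f_gt = int(mothers[k]), int(fathers[k])
                child_gt, mat_allele, pat_allele = simulate_offspring(m_gt, f_gt, rng)
                genotypes.at[fam.mother_sample, snp_id] = m_gt
                if fam.father_sample is not None:
                    genotypes.at[fam.father_sample, snp_id] = f_gt
                genotypes.at[fam.placenta_sample, snp_id] = child_gt
                phase_rows.append(
                    {
                        "family_id": fam.family_id,
                        "snp_id": snp_id,
                        "maternal_allele": _ALLELE_LABEL[mat_allele],
                        "paternal_allele": _ALLELE_LABEL[pat_allele],
                    }
                )
                ref, alt = simulate_allelic_reads(
                    mat_allele, pat_allele, m_gt, gene.theta, gene.mean_depth, noise, rng
                )
                count_rows.append(
                    {
                        "sample": fam.placenta_sample,
                        "snp_id": snp_id,
                        "ref_count": ref,
                        "alt_count": alt,
                    }
                )

    placenta_samples = [f.placenta_sample for f in families]
    lib_factors = rng.lognormal(mean=0.0, sigma=0.2, size=len(placenta_samples))
    gene_counts = pd.DataFrame(
        {
            s: rng.poisson([g.mean_expression * lib_factors[i] for g in genes])
            for i, s in enumerate(placenta_samples)
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    gene_lengths = pd.Series(
        [g.gene_length_bp for g in genes],
        index=gene_counts.index,
        name="length_bp",
        dtype=np.int64,
    )

    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "theta": [g.theta for g in genes],
            "true_class": [true_class(g.theta) for g in genes],
        }
    )
    truth = SimTruth(
        genes=truth_genes,
        phase=pd.DataFrame(
            phase_rows,
            columns=["family_id", "snp_id", "maternal_allele", "paternal_allele"],
        ),
        seed=seed,
    )
    return CohortBundle(
        families=families,
        genotype_table=GenotypeTable(genotypes=genotypes, snps=snps, rejected_sites=[]),
        snp_genes=pd.Series(snp_genes, name="gene_id"),
        exons=exons,
        allelic_counts=pd.DataFrame(
            count_rows, columns=["sample", "snp_id", "ref_count", "alt_count"]
        ),
        gene_counts=gene_counts,
        gene_lengths=gene_lengths,
        truth=truth,
    )


def write_cohort(bundle: CohortBundle, out_dir) -> Dict[str, Path]:
    """Materialize a simulated cohort as the standard file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "pedigree": out / "pedigree.tsv",
        "allelic_counts": out / "allelic_counts.tsv",
        "gene_counts": out / "gene_counts.tsv",
        "exons": out / "exons.bed",
        "truth_genes": out / "truth_genes.tsv",
        "truth_phase": out / "truth_phase.tsv",
    }
    write_genotypes_vcf(bundle.genotype_table, paths["vcf"])
    write_pedigree(bundle.families, paths["pedigree"])
    write_allelic_counts(bundle.allelic_counts, paths["allelic_counts"])
    write_gene_counts(bundle.gene_counts, bundle.gene_lengths, paths["gene_counts"])
    write_exon_bed(bundle.exons, paths["exons"])
    bundle.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    bundle.truth.phase.to_csv(paths["truth_phase"], sep="\t", index=False)
    return paths
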