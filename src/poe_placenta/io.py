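"""Readers and writers for the formats the pipeline touches.

Genotypes come in as VCF (decoded with cyvcf2), exon intervals as BED
(0-based half-open), and the pedigree, allelic read counts and the
gene-level count matrix as headered TSV.  All outputs are TSV so that a
round trip through disk is bit-exact.

Coordinate convention: a BED interval [start, end) contains a 1-based VCF
position ``pos`` iff ``start < pos <= end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from poe_placenta.config import CLINICAL_GROUPS, Genotype, TrioFamily

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class GenotypeTable:
    """Cohort genotypes: a samples x SNPs dosage matrix plus site metadata.

    ``genotypes`` holds alternate-allele dosages (0/1/2, -1 for missing);
    ``snps`` has one row per retained site with columns
    snp_id, chrom, pos (1-based), ref_allele, alt_allele.
    """

    genotypes: pd.DataFrame
    snps: pd.DataFrame
    rejected_sites: List[str]


def read_genotypes(vcf_path: PathLike) -> GenotypeTable:
    """Decode GT fields of a VCF into a dosage matrix.

    Multi-allelic sites and non-SNV records violate the biallelic-SNP
    contract and are rejected with a log entry rather than an error.
    """
    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except Exception as exc:  # cyvcf2 raises plain OSError/Exception
        raise ValueError(f"malformed or unreadable VCF {vcf_path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: List[Dict[str, object]] = []
    dosages: List[np.ndarray] = []
    rejected: List[str] = []
    for variant in vcf:
        site = f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            rejected.append(site)
            logger.warning("rejecting multi-allelic site %s (ALT=%s)", site, variant.ALT)
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            rejected.append(site)
            logger.warning("rejecting non-SNV site %s (%s>%s)", site, ref, alt)
            continue
        snp_id = variant.ID if variant.ID not in (None, ".") else site
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref_allele": ref,
                "alt_allele": alt,
            }
        )
        # gts012: 0=hom_ref, 1=het, 2=hom_alt, 3=unknown
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = Genotype.MISSING
        dosages.append(gt)
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref_allele", "alt_allele"])
    if snps["snp_id"].duplicated().any():
        dup = snps.loc[snps["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate SNP identifier {dup!r} in {vcf_path}")
    matrix = (
        pd.DataFrame(
            np.column_stack(dosages) if dosages else np.empty((len(samples), 0), dtype=np.int8),
            index=pd.Index(samples, name="sample"),
            columns=snps["snp_id"].tolist(),
        )
        .astype(np.int8)
    )
    return GenotypeTable(genotypes=matrix, snps=snps, rejected_sites=rejected)


_GT_STRINGS = {
    int(Genotype.HOM_REF): "0/0",
    int(Genotype.HET): "0/1",
    int(Genotype.HOM_ALT): "1/1",
    int(Genotype.MISSING): "./.",
}


def write_genotypes_vcf(table: GenotypeTable, vcf_path: PathLike) -> None:
    """Emit a minimal valid VCF 4.2 with GT-only FORMAT fields."""
    samples = list(table.genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in pd.unique(table.snps["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for row in table.snps.itertuples(index=False):
        gts = [_GT_STRINGS[int(table.genotypes.at[s, row.snp_id])] for s in samples]
        lines.append(
            f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref_allele}\t{row.alt_allele}"
            "\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")


_PED_COLUMNS = [
    "family_id",
    "placenta",
    "mother",
    "father",
    "clinical_group",
    "gestational_age_days",
]


def read_pedigree(ped_path: PathLike) -> List[TrioFamily]:
    """Read the family table; a father of "0" or empty marks a duo."""
    df = pd.read_csv(ped_path, sep="\t", dtype=str)
    missing = [c for c in _PED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pedigree {ped_path} lacks required columns {missing}")
    if df["family_id"].duplicated().any():
        dup = df.loc[df["family_id"].duplicated(), "family_id"].iloc[0]
        raise ValueError(f"duplicate family_id {dup!r} in pedigree")
    if df["placenta"].duplicated().any():
        dup = df.loc[df["placenta"].duplicated(), "placenta"].iloc[0]
        raise ValueError(f"placenta sample {dup!r} referenced by two families")
    families = []
    for row in df.itertuples(index=False):
        father = row.father
        if father is None or pd.isna(father) or father in ("0", ""):
            father = None
        if row.clinical_group not in CLINICAL_GROUPS:
            raise ValueError(
                f"unknown clinical group {row.clinical_group!r} for family {row.family_id}"
            )
        families.append(
            TrioFamily(
                family_id=row.family_id,
                placenta_sample=row.placenta,
                mother_sample=row.mother,
                father_sample=father,
                clinical_group=row.clinical_group,
                gestational_age_days=int(row.gestational_age_days),
            )
        )
    return families


def write_pedigree(families: Sequence[TrioFamily], ped_path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "placenta": f.placenta_sample,
                "mother": f.mother_sample,
                "father": f.father_sample if f.father_sample is not None else "0",
                "clinical_group": f.clinical_group,
                "gestational_age_days": f.gestational_age_days,
            }
            for f in families
        ],
        columns=_PED_COLUMNS,
    )
    df.to_csv(ped_path, sep="\t", index=False)


def read_allelic_counts(tsv_path: PathLike) -> pd.DataFrame:
    """Read per-sample per-SNP ref/alt read tallies (tabulated pileup output).

    Returns a DataFrame with columns sample, snp_id, ref_count, alt_count,
    one row per (sample, SNP).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample": str, "snp_id": str})
    required = ["sample", "snp_id", "ref_count", "alt_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"allelic count table {tsv_path} lacks columns {missing}")
    if df.empty:
        logger.warning("allelic count table %s is empty", tsv_path)
        return df[required]
    for col in ("ref_count", "alt_count"):
        counts = pd.to_numeric(df[col], errors="raise")
        if (counts < 0).any() or not np.allclose(counts, counts.astype(np.int64)):
            raise ValueError(f"{col} must hold non-negative integers")
        df[col] = counts.astype(np.int64)
    if df.duplicated(subset=["sample", "snp_id"]).any():
        key = df.loc[df.duplicated(subset=["sample", "snp_id"]), ["sample", "snp_id"]].iloc[0]
        raise ValueError(f"duplicate allelic count record for {tuple(key)}")
    return df[required]


def write_allelic_counts(counts: pd.DataFrame, tsv_path: PathLike) -> None:
    counts.to_csv(tsv_path, sep="\t", index=False)


def read_exon_bed(bed_path: PathLike) -> pd.DataFrame:
    """Read exon intervals (BED, 0-based half-open) keyed by gene (column 4)."""
    df = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "gene_id": str},
    )
    bad = df[df["start"] >= df["end"]]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"invalid BED interval {row.chrom}:{row.start}-{row.end} (start >= end)"
        )
    return df


def write_exon_bed(exons: pd.DataFrame, bed_path: PathLike) -> None:
    exons[["chrom", "start", "end", "gene_id"]].to_csv(
        bed_path, sep="\t", index=False, header=False
    )


def bed_contains(start: int, end: int, pos_1based: int) -> bool:
    """Whether a 0-based half-open [start, end) interval covers a 1-based position."""
    return start < pos_1based <= end


def read_gene_counts(tsv_path: PathLike) -> Tuple[pd.DataFrame, pd.Series]:
    """Read the genes x samples raw count matrix.

    The first column is gene_id; an optional ``length_bp`` column carries
    gene lengths for FPKM computation (all-NaN if absent).
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"gene count matrix {tsv_path} lacks a gene_id column")
    df = df.set_index("gene_id")
    if "length_bp" in df.columns:
        lengths = df.pop("length_bp").astype(np.int64)
    else:
        lengths = pd.Series(np.nan, index=df.index, name="length_bp")
    counts = df.astype(np.int64)
    if (counts < 0).to_numpy().any():
        raise ValueError("gene counts must be non-negative")
    return counts, lengths


def write_gene_counts(counts: pd.DataFrame, lengths: pd.Series, tsv_path: PathLike) -> None:
    out = counts.copy()
    out.insert(0, "length_bp", lengths)
    out.to_csv(tsv_path, sep="\t", index_label="gene_id")
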