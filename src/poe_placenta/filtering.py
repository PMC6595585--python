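"""The gene- and SNP-level filtering cascade.

Candidate genes are whittled down in ordered stages — annotation,
expression level, presence of a common exonic SNP in Hardy-Weinberg
equilibrium, informative families, read coverage — and every dropout is
logged with exactly one reason, so the stage-by-stage bookkeeping is
auditable: gene sets are strictly nested and dropouts plus survivors sum
to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from poe_placenta.config import CohortConfig, Genotype
from poe_placenta.io import bed_contains


@dataclass
class FilterStage:
    name: str
    genes_in: Set[str]
    genes_out: Set[str]
    dropped: Dict[str, str]  # gene -> reason


@dataclass
class FilterTrace:
    """Ordered record of the filtering cascade, gene-level."""

    stages: List[FilterStage] = field(default_factory=list)

    def add_stage(self, name: str, genes_in: Set[str], dropped: Dict[str, str]) -> Set[str]:
        unknown = set(dropped) - genes_in
        if unknown:
            raise ValueError(f"stage {name!r} drops genes not in its input: {unknown}")
        genes_out = genes_in - set(dropped)
        if self.stages and genes_in != self.stages[-1].genes_out:
            raise ValueError(f"stage {name!r} input differs from previous stage output")
        self.stages.append(FilterStage(name, set(genes_in), genes_out, dict(dropped)))
        return genes_out

    @property
    def survivors(self) -> Set[str]:
        return set(self.stages[-1].genes_out) if self.stages else set()

    def is_nested(self) -> bool:
        return all(s.genes_out <= s.genes_in for s in self.stages) and all(
            self.stages[i + 1].genes_in == self.stages[i].genes_out
            for i in range(len(self.stages) - 1)
        )

    def conserves_counts(self) -> bool:
        if not self.stages:
            return True
        total_dropped = sum(len(s.dropped) for s in self.stages)
        return len(self.stages[0].genes_in) == total_dropped + len(self.survivors)

    def dropout_reasons(self) -> Dict[str, str]:
        reasons: Dict[str, str] = {}
        for stage in self.stages:
            reasons.update(stage.dropped)
        return reasons

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage in self.stages:
            for gene in sorted(stage.dropped):
                rows.append(
                    {"stage": stage.name, "gene_id": gene, "reason": stage.dropped[gene]}
                )
        return pd.DataFrame(rows, columns=["stage", "gene_id", "reason"])


# --------------------------------------------------------------------------
# expression filters


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples raw count matrix).

    factor_s = median over reference genes g of count_gs / geometric mean
    of gene g across samples; reference genes are those with nonzero
    counts in every sample.
    """
    expressed = counts[(counts > 0).all(axis=1)]
    if expressed.empty:
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "consider a pseudo-reference fallback"
        )
    log_counts = np.log(expressed.to_numpy(dtype=np.float64))
    log_geo_mean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    return counts / size_factors


def filter_genes_by_expression(
    counts: pd.DataFrame, size_factors: pd.Series, threshold: float
) -> Tuple[Set[str], Dict[str, str]]:
    """Keep genes whose median normalized count reaches the threshold.

    The dropout is strict: a gene is discarded iff its median normalized
    expression is below the threshold (median exactly at the threshold is
    retained).
    """
    medians = normalize_counts(counts, size_factors).median(axis=1)
    dropped = {g: "low_expression" for g in medians.index[medians < threshold]}
    retained = set(medians.index) - set(dropped)
    return retained, dropped


def compute_fpkm(
    gene_reads, gene_length_bp, total_mapped_reads
):
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM = reads * 1e9 / (length_bp * total_mapped_reads); accepts scalars
    or aligned arrays.
    """
    length = np.asarray(gene_length_bp, dtype=np.float64)
    total = np.asarray(total_mapped_reads, dtype=np.float64)
    if np.any(length <= 0) or np.any(total <= 0):
        raise ValueError("gene length and total mapped reads must be positive")
    result = np.asarray(gene_reads, dtype=np.float64) * 1e9 / (length * total)
    return result.item() if result.ndim == 0 else result


def fpkm_stats(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Per-gene FPKM mean and SD across samples (library size per sample)."""
    totals = counts.sum(axis=0)
    fpkm = counts * 1e9 / np.outer(lengths, totals)
    return pd.DataFrame(
        {"fpkm_mean": fpkm.mean(axis=1), "fpkm_sd": fpkm.std(axis=1, ddof=1)},
        index=counts.index,
    )


# --------------------------------------------------------------------------
# SNP-level filters


def compute_maf(genotypes: Iterable[int]) -> float:
    """Minor allele frequency from alt-allele dosages, missing excluded."""
    dosages = np.asarray(list(genotypes), dtype=np.int64)
    dosages = dosages[dosages != Genotype.MISSING]
    if dosages.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    alt_freq = dosages.sum() / (2 * dosages.size)
    return float(min(alt_freq, 1.0 - alt_freq))


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) goodness-of-fit test of Hardy-Weinberg equilibrium.

    Expected genotype counts are p^2, 2pq, q^2 at the sample allele
    frequency.  Monomorphic SNPs have no testable departure and return
    p = 1.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("HWE test requires at least one genotype")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=np.float64)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_genotypes(genotypes: Iterable[int]) -> float:
    dosages = np.asarray(list(genotypes), dtype=np.int64)
    dosages = dosages[dosages != Genotype.MISSING]
    if dosages.size == 0:
        raise ValueError("HWE test undefined: all genotypes missing")
    return hwe_test(
        int((dosages == 0).sum()), int((dosages == 1).sum()), int((dosages == 2).sum())
    )


def select_exonic_snps(
    snps: pd.DataFrame,
    exons: pd.DataFrame,
    exclusion_list: Iterable[str] = (),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Assign SNPs to genes via exon intersection, applying exclusions.

    A SNP is retained iff its 1-based position falls inside at least one
    exon interval (BED half-open convention) and its identifier is not on
    the manual exclusion list (the stand-in for curation of SNPs in
    alternative exons).  Returns (retained SNPs with a gene_id column,
    dropped SNPs with a reason column).
    """
    excluded = set(exclusion_list)
    retained_rows = []
    dropped_rows = []
    for snp in snps.itertuples(index=False):
        if snp.snp_id in excluded:
            dropped_rows.append({"snp_id": snp.snp_id, "reason": "manual_exclusion"})
            continue
        hits = exons[
            (exons["chrom"] == snp.chrom)
            & (exons["start"] < snp.pos)
            & (snp.pos <= exons["end"])
        ]
        gene_ids = sorted(hits["gene_id"].unique())
        if not gene_ids:
            dropped_rows.append({"snp_id": snp.snp_id, "reason": "unannotated"})
            continue
        rec = snp._asdict()
        rec["gene_id"] = gene_ids[0]
        retained_rows.append(rec)
    retained = pd.DataFrame(
        retained_rows,
        columns=list(snps.columns) + ["gene_id"],
    )
    dropped = pd.DataFrame(dropped_rows, columns=["snp_id", "reason"])
    return retained, dropped


def filter_snps_by_frequency(
    genotypes: pd.DataFrame,
    snp_ids: Sequence[str],
    config: CohortConfig,
) -> Tuple[List[str], pd.DataFrame]:
    """Apply the common-variant filters: MAF strictly above threshold and
    Hardy-Weinberg equilibrium p strictly above alpha.

    Returns the retained SNP ids and a table of dropped SNPs with reasons
    (a SNP failing both filters is charged to the MAF stage, the first one
    applied).
    """
    retained: List[str] = []
    dropped_rows = []
    for snp in snp_ids:
        dosages = genotypes[snp].to_numpy()
        non_missing = dosages[dosages != Genotype.MISSING]
        if non_missing.size == 0:
            dropped_rows.append({"snp_id": snp, "reason": "all_missing"})
            continue
        if compute_maf(non_missing) <= config.maf_threshold:
            dropped_rows.append({"snp_id": snp, "reason": "low_maf"})
            continue
        if hwe_test_genotypes(non_missing) <= config.hwe_alpha:
            dropped_rows.append({"snp_id": snp, "reason": "hwe_violation"})
            continue
        retained.append(snp)
    return retained, pd.DataFrame(dropped_rows, columns=["snp_id", "reason"])
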