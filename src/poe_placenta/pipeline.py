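"""End-to-end orchestration: filtering cascade -> phasing -> gene statistics.

``run_pipeline`` takes the five standard inputs (genotypes, pedigree,
exons, allelic counts, gene count matrix) either in memory or as a
simulated :class:`~poe_placenta.simulate.CohortBundle`, applies the
candidate filters stage by stage with full dropout bookkeeping, assigns
parental origin per family and SNP, and produces the gene-level
summaries, class medians and per-clinical-group breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

from poe_placenta.analysis import (
    build_parental_counts,
    class_summary,
    filter_snp_by_coverage,
    group_breakdown,
    summarize_genes,
)
from poe_placenta.config import CohortConfig, TrioFamily
from poe_placenta.filtering import (
    FilterTrace,
    compute_size_factors,
    filter_genes_by_expression,
    filter_snps_by_frequency,
    fpkm_stats,
    select_exonic_snps,
)
from poe_placenta.io import GenotypeTable
from poe_placenta.phasing import call_cohort, informative_snps
from poe_placenta.simulate import CohortBundle


@dataclass
class PipelineResult:
    trace: FilterTrace
    snp_dropouts: pd.DataFrame  # snp_id, reason
    calls: pd.DataFrame
    parental_counts: pd.DataFrame
    summaries: pd.DataFrame
    class_summaries: pd.DataFrame
    groups: pd.DataFrame
    expression_stats: Optional[pd.DataFrame]
    n_tests: int


def run_pipeline(
    genotype_table: GenotypeTable,
    families: Sequence[TrioFamily],
    exons: pd.DataFrame,
    allelic_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    gene_lengths: Optional[pd.Series] = None,
    config: Optional[CohortConfig] = None,
    seed: int = 0,
) -> PipelineResult:
    if config is None:
        config = CohortConfig()
    trace = FilterTrace()
    snp_dropout_frames: List[pd.DataFrame] = []

    # Stage 1 — annotation: a candidate needs exon records and a count row.
    candidates = set(gene_counts.index) | set(exons["gene_id"])
    dropped = {
        g: "unannotated"
        for g in candidates
        if g not in set(exons["gene_id"]) or g not in gene_counts.index
    }
    retained = trace.add_stage("annotation", candidates, dropped)

    # Stage 2 — expression: median normalized count must reach the threshold.
    counts = gene_counts.loc[sorted(retained)]
    size_factors = compute_size_factors(counts)
    _, expr_dropped = filter_genes_by_expression(
        counts, size_factors, config.expression_median_threshold
    )
    retained = trace.add_stage("expression", retained, expr_dropped)

    # Stage 3 — common exonic SNPs: exon intersection, manual exclusions,
    # MAF and Hardy-Weinberg filters; genes keep >= 1 qualifying SNP.
    snps_with_genes, exon_dropped = select_exonic_snps(
        genotype_table.snps, exons, config.snp_exclusion_list
    )
    if not exon_dropped.empty:
        snp_dropout_frames.append(exon_dropped)
    snps_with_genes = snps_with_genes[snps_with_genes["gene_id"].isin(retained)]
    freq_retained, freq_dropped = filter_snps_by_frequency(
        genotype_table.genotypes, snps_with_genes["snp_id"].tolist(), config
    )
    if not freq_dropped.empty:
        snp_dropout_frames.append(freq_dropped)
    snp_genes = snps_with_genes.set_index("snp_id")["gene_id"].loc[freq_retained]
    dropped = {
        g: "no_common_exonic_snp" for g in retained if g not in set(snp_genes.values)
    }
    retained = trace.add_stage("common_exonic_snp", retained, dropped)

    # Stage 4 — informative families: SNPs informative for >= the minimum
    # number of trios/duos; genes keep >= 1 such SNP.
    calls = call_cohort(
        genotype_table.genotypes,
        families,
        snp_genes.index.tolist(),
        father_hom_informative=config.father_hom_informative,
    )
    passing = informative_snps(calls, config)
    under_informative = [s for s in snp_genes.index if s not in set(passing)]
    if under_informative:
        snp_dropout_frames.append(
            pd.DataFrame(
                {"snp_id": under_informative, "reason": "under_informative"}
            )
        )
    snp_genes = snp_genes.loc[[s for s in snp_genes.index if s in set(passing)]]
    dropped = {
        g: "insufficient_informative_families"
        for g in retained
        if g not in set(snp_genes.values)
    }
    retained = trace.add_stage("informative_families", retained, dropped)

    # Stage 5 — coverage: median reads across informative placentas.
    parental_counts = build_parental_counts(allelic_counts, calls, families, snp_genes)
    covered = filter_snp_by_coverage(parental_counts, config.min_median_reads)
    low_cov = [s for s in snp_genes.index if s not in set(covered)]
    if low_cov:
        snp_dropout_frames.append(
            pd.DataFrame({"snp_id": low_cov, "reason": "low_coverage"})
        )
    snp_genes = snp_genes.loc[[s for s in snp_genes.index if s in set(covered)]]
    parental_counts = parental_counts[parental_counts["snp_id"].isin(snp_genes.index)]
    dropped = {
        g: "low_snp_coverage" for g in retained if g not in set(snp_genes.values)
    }
    retained = trace.add_stage("snp_coverage", retained, dropped)

    # Final testable set: genes with enough distinct families and any reads.
    summaries = summarize_genes(parental_counts, config, families=families, seed=seed)
    tested = set(summaries["gene_id"])
    dropped = {g: "no_usable_reads" for g in retained if g not in tested}
    trace.add_stage("testable", retained, dropped)

    groups = group_breakdown(
        parental_counts[parental_counts["gene_id"].isin(tested)], families, config
    )
    expression_stats = None
    if gene_lengths is not None and gene_lengths.notna().any():
        expression_stats = fpkm_stats(
            gene_counts.loc[sorted(tested & set(gene_counts.index))],
            gene_lengths.loc[sorted(tested & set(gene_counts.index))],
        )
    snp_dropouts = (
        pd.concat(snp_dropout_frames, ignore_index=True)
        if snp_dropout_frames
        else pd.DataFrame(columns=["snp_id", "reason"])
    )
    return PipelineResult(
        trace=trace,
        snp_dropouts=snp_dropouts,
        calls=calls,
        parental_counts=parental_counts.reset_index(drop=True),
        summaries=summaries,
        class_summaries=class_summary(summaries),
        groups=groups,
        expression_stats=expression_stats,
        n_tests=config.n_tests_bonferroni or len(summaries),
    )


def run_pipeline_on_bundle(
    bundle: CohortBundle, config: Optional[CohortConfig] = None, seed: int = 0
) -> PipelineResult:
    """Convenience wrapper for a simulated cohort."""
    return run_pipeline(
        genotype_table=bundle.genotype_table,
        families=bundle.families,
        exons=bundle.exons,
        allelic_counts=bundle.allelic_counts,
        gene_counts=bundle.gene_counts,
        gene_lengths=bundle.gene_lengths,
        config=config,
        seed=seed,
    )
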