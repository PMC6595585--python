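"""Shared fixtures: simulated cohorts and a planted filtering fixture."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import pytest

from poe_placenta.config import Genotype
from poe_placenta.simulate import (
    CohortBundle,
    GeneModel,
    NoiseModel,
    default_table1_families,
    generate_cohort,
)


@pytest.fixture(scope="session")
def table1_bundle() -> CohortBundle:
    """Default 54-family, 25-gene cohort used by several suites."""
    return generate_cohort(seed=11)


@pytest.fixture(scope="session")
def planted_filter_bundle() -> Tuple[CohortBundle, Dict[str, str]]:
    """A 50-gene cohort with deliberately planted filter failures.

    Returns the bundle plus the expected gene -> dropout-reason map.
    Planted failures: genes without exon annotation, genes below the
    expression threshold, and genes whose single SNP fails the MAF, HWE,
    informativeness or coverage filter.  Genotype-level plants are written
    directly into the genotype matrix so the dropout is deterministic.
    """
    genes: List[GeneModel] = []
    expected: Dict[str, str] = {}

    def add(prefix: str, count: int, reason: str, n_snps: int = 2, **kwargs) -> List[str]:
        # genes whose genotypes stay HWE-drawn get two SNPs so that the
        # HWE filter's inherent ~5% false-positive rate cannot drop them;
        # genes with planted genotype patterns use a single SNP
        ids = []
        for i in range(1, count + 1):
            gid = f"{prefix}{i:02d}"
            genes.append(GeneModel(gene_id=gid, theta=0.5, n_snps=n_snps, **kwargs))
            if reason:
                expected[gid] = reason
            ids.append(gid)
        return ids

    add("ANNO", 3, "unannotated")
    add("LOWX", 5, "low_expression", mean_expression=5.0)
    maf_genes = add("LMAF", 4, "no_common_exonic_snp", n_snps=1)
    hwe_genes = add("LHWE", 4, "no_common_exonic_snp", n_snps=1)
    uninf_genes = add("UNIN", 4, "insufficient_informative_families", n_snps=1)
    add("LCOV", 4, "low_snp_coverage", mean_depth=0.3)
    add("PASS", 26, "")

    families = default_table1_families(np.random.default_rng(5))
    bundle = generate_cohort(
        families=families, genes=genes, noise=NoiseModel(), seed=23
    )

    # plant: drop exon annotation for the ANNO genes
    bundle.exons = bundle.exons[~bundle.exons["gene_id"].str.startswith("ANNO")]

    gmat = bundle.genotype_table.genotypes
    n_samples = len(gmat.index)
    for gid in maf_genes:
        snp = f"{gid}_snp1"  # two carriers only: cohort MAF ~1%, below 10%
        col = np.full(n_samples, Genotype.HOM_REF, dtype=np.int8)
        col[:2] = Genotype.HET
        gmat[snp] = col
    for gid in hwe_genes:
        snp = f"{gid}_snp1"  # all homozygotes, no hets: extreme HWE departure
        col = np.full(n_samples, Genotype.HOM_REF, dtype=np.int8)
        col[n_samples // 2 :] = Genotype.HOM_ALT
        gmat[snp] = col
    placentas = {f.placenta_sample for f in families}
    is_placenta = np.array([s in placentas for s in gmat.index])
    for gid in uninf_genes:
        # quarter hom_ref, quarter hom_alt, half het everywhere (perfect
        # HWE at MAF 0.5) and placenta genotypes matching, so no family
        # has a homozygous parent with a het placenta
        snp = f"{gid}_snp1"
        col = np.empty(n_samples, dtype=np.int8)
        pattern = [Genotype.HOM_REF, Genotype.HET, Genotype.HET, Genotype.HOM_ALT]
        for i in range(n_samples):
            col[i] = pattern[i % 4]
        gmat[snp] = col
        # rewrite per family so parents and placenta share the pattern slot
        for j, fam in enumerate(families):
            gt = pattern[j % 4]
            gmat.at[fam.placenta_sample, snp] = gt
            gmat.at[fam.mother_sample, snp] = gt
            if fam.father_sample is not None:
                gmat.at[fam.father_sample, snp] = gt
    return bundle, expected
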