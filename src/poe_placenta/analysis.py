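"""Gene-level parental read statistics, the exact binomial test, and the
three-way imprinting classification.

For each gene, maternal (Mat) and paternal (Pat) read counts are summed
over all informative families and coverage-passing SNPs.  The pooled
maternal read proportion theta-hat = Mat / (Mat + Pat) is tested against
the biallelic expectation of 0.5 with an exact two-sided binomial test,
Bonferroni-corrected over the number of genes tested.  Classification:

* imprinted  — significant and > 90% of reads from one parental allele;
* biased     — significant and 65-90% of reads from one parental allele;
* biallelic  — otherwise (no significant deviation and/or both parental
  proportions inside the 35-65% band).
"""

from __future__ import annotations

import enum
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from poe_placenta.config import CLINICAL_GROUPS, CohortConfig, TrioFamily
from poe_placenta.phasing import InformativeStatus


class LocusClass(str, enum.Enum):
    IMPRINTED = "imprinted"
    BIASED = "biased"
    BIALLELIC = "biallelic"


class ExpressedParent(str, enum.Enum):
    MAT = "Mat"
    PAT = "Pat"
    BOTH = "both"


# --------------------------------------------------------------------------
# per-(family, SNP) parental counts


def map_counts_to_parents(
    ref_count: int, alt_count: int, maternal_allele: str, paternal_allele: str
) -> Tuple[int, int]:
    """Relabel ref/alt read tallies as maternal/paternal reads.

    Only meaningful for informative calls; the caller must pre-filter.
    """
    if {maternal_allele, paternal_allele} != {"ref", "alt"}:
        raise ValueError("parental alleles must be a ref/alt pair from an informative call")
    if maternal_allele == "ref":
        return int(ref_count), int(alt_count)
    return int(alt_count), int(ref_count)


def build_parental_counts(
    allelic_counts: pd.DataFrame,
    calls: pd.DataFrame,
    families: Sequence[TrioFamily],
    snp_genes: pd.Series,
) -> pd.DataFrame:
    """Join informative calls with placental allele tallies.

    ``snp_genes`` maps snp_id -> gene_id.  (Family, SNP) pairs without a
    tallied count get zero reads (zero-coverage site).  Returns columns
    family_id, snp_id, gene_id, mat_reads, pat_reads.
    """
    placenta_of = {f.family_id: f.placenta_sample for f in families}
    informative = calls[calls["status"] == InformativeStatus.INFORMATIVE.value].copy()
    informative = informative[informative["snp_id"].isin(snp_genes.index)]
    informative["sample"] = informative["family_id"].map(placenta_of)
    informative = informative[informative["sample"].notna()]
    merged = informative.merge(allelic_counts, on=["sample", "snp_id"], how="left")
    # (family, SNP) pairs without a tallied record are zero-coverage sites
    merged[["ref_count", "alt_count"]] = (
        merged[["ref_count", "alt_count"]].fillna(0).astype(np.int64)
    )
    maternal_is_ref = merged["maternal_allele"] == "ref"
    merged["mat_reads"] = np.where(maternal_is_ref, merged["ref_count"], merged["alt_count"])
    merged["pat_reads"] = np.where(maternal_is_ref, merged["alt_count"], merged["ref_count"])
    merged["gene_id"] = merged["snp_id"].map(snp_genes)
    return merged[["family_id", "snp_id", "gene_id", "mat_reads", "pat_reads"]].copy()


def filter_snp_by_coverage(parental_counts: pd.DataFrame, min_median_reads: int) -> pd.Index:
    """SNPs whose median total reads across informative placentas is adequate.

    The median is over per-placenta (mat + pat) totals; SNPs with a median
    below ``min_median_reads`` are discarded (strict "<" dropout).
    """
    totals = parental_counts.assign(
        total=parental_counts["mat_reads"] + parental_counts["pat_reads"]
    )
    medians = totals.groupby("snp_id")["total"].median()
    return medians.index[medians >= min_median_reads]


def aggregate_gene(parental_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum Mat/Pat reads over all (family, SNP) records of each gene."""
    if parental_counts.empty:
        return pd.DataFrame(
            columns=["gene_id", "mat_total", "pat_total", "n_informative_families"]
        )
    grouped = parental_counts.groupby("gene_id")
    out = grouped[["mat_reads", "pat_reads"]].sum()
    out.columns = ["mat_total", "pat_total"]
    out["n_informative_families"] = grouped["family_id"].nunique()
    return out.reset_index()


# --------------------------------------------------------------------------
# statistics


def binomial_test_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test of k successes in n trials vs p0.

    Follows the minimum-likelihood convention (the sum of probabilities of
    all outcomes whose point probability does not exceed that of ``k``,
    with relative tolerance 1e-7), which is how R's binom.test defines the
    two-sided p-value.  For p0 = 0.5 this reduces to twice the smaller
    tail, capped at 1.
    """
    if n < 1:
        raise ValueError("binomial test requires at least one trial")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("null proportion must lie in (0, 1)")
    if p0 == 0.5:
        lower = stats.binom.cdf(k, n, p0)
        upper = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    # general p0: enumerate outcomes at most as likely as the observed one
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    threshold = pmf[k] * (1.0 + 1e-7)
    return float(min(1.0, pmf[pmf <= threshold].sum()))


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise error control: p_corr = min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    return min(1.0, m * p_raw)


def proportion_ci(
    k: int,
    n: int,
    method: str = "clopper_pearson",
    alpha: float = 0.05,
    family_counts: Optional[pd.DataFrame] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Confidence interval for the pooled maternal read proportion.

    ``clopper_pearson`` and ``wilson`` are the standard closed-form
    intervals on the pooled counts.  ``bootstrap`` resamples whole
    families (the natural exchangeable unit: reads within a family share
    its phase and coverage) and takes the percentile interval of the
    re-pooled proportion; it requires per-family counts.
    """
    if n < 1:
        raise ValueError("confidence interval requires n >= 1")
    if method == "clopper_pearson":
        low, high = proportion_confint(k, n, alpha=alpha, method="beta")
    elif method == "wilson":
        low, high = proportion_confint(k, n, alpha=alpha, method="wilson")
    elif method == "bootstrap":
        if family_counts is None or family_counts.empty:
            raise ValueError("bootstrap CI needs per-family mat/pat counts")
        rng = np.random.default_rng(seed)
        per_family = family_counts.groupby("family_id")[["mat_reads", "pat_reads"]].sum()
        mats = per_family["mat_reads"].to_numpy(dtype=np.float64)
        tots = (per_family["mat_reads"] + per_family["pat_reads"]).to_numpy(dtype=np.float64)
        n_fam = len(per_family)
        idx = rng.integers(0, n_fam, size=(n_boot, n_fam))
        boot_tot = tots[idx].sum(axis=1)
        boot_mat = mats[idx].sum(axis=1)
        props = np.divide(boot_mat, boot_tot, out=np.full(n_boot, np.nan), where=boot_tot > 0)
        props = props[~np.isnan(props)]
        low, high = np.quantile(props, [alpha / 2, 1 - alpha / 2])
        point = k / n
        low, high = min(low, point), max(high, point)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(max(0.0, low)), float(min(1.0, high))


def classify_gene(
    mat_proportion: float, p_corr: float, config: CohortConfig
) -> Tuple[LocusClass, ExpressedParent]:
    """Three-way classification from the pooled proportion and corrected p.

    The preferred-allele fraction f = max(theta-hat, 1 - theta-hat) is
    gated by significance: without a significant deviation from 0.5 the
    gene is biallelic regardless of f.  Imprinted requires f strictly
    above the monoallelic threshold; the biased band is closed at both
    ends so the three classes partition [0.5, 1].
    """
    f = max(mat_proportion, 1.0 - mat_proportion)
    if p_corr < config.alpha and f > config.imprinted_threshold:
        cls = LocusClass.IMPRINTED
    elif p_corr < config.alpha and config.biased_low <= f <= config.imprinted_threshold:
        cls = LocusClass.BIASED
    else:
        cls = LocusClass.BIALLELIC
    if cls is LocusClass.BIALLELIC:
        parent = ExpressedParent.BOTH
    elif mat_proportion > 0.5:
        parent = ExpressedParent.MAT
    else:
        parent = ExpressedParent.PAT
    return cls, parent


# --------------------------------------------------------------------------
# gene summaries


def summarize_genes(
    parental_counts: pd.DataFrame,
    config: CohortConfig,
    families: Optional[Sequence[TrioFamily]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-gene summary: totals, proportion, CI, p-values, class.

    ``parental_counts`` must already be restricted to informative calls
    and coverage-passing SNPs.  Genes with fewer than
    ``min_informative_families`` distinct families are excluded before
    testing, and the Bonferroni divisor m is the number of genes that
    reach the testing stage (``config.n_tests_bonferroni`` overrides it
    when the run is a re-analysis of a larger published test set).
    """
    agg = aggregate_gene(parental_counts)
    agg = agg[agg["n_informative_families"] >= config.min_informative_families]
    agg = agg[(agg["mat_total"] + agg["pat_total"]) > 0].reset_index(drop=True)
    if agg.empty:
        return pd.DataFrame(
            columns=[
                "gene_id", "mat_total", "pat_total", "mat_proportion",
                "ci_low", "ci_high", "p_raw", "p_corr", "preferred_fraction",
                "locus_class", "expressed_parent", "n_informative_families",
            ]
        )
    m = config.n_tests_bonferroni or len(agg)
    rows = []
    for rec in agg.itertuples(index=False):
        mat, pat = int(rec.mat_total), int(rec.pat_total)
        n = mat + pat
        prop = mat / n
        p_raw = binomial_test_two_sided(mat, n)
        p_corr = bonferroni(p_raw, m)
        fam_counts = parental_counts[parental_counts["gene_id"] == rec.gene_id]
        ci_low, ci_high = proportion_ci(
            mat,
            n,
            method=config.ci_method,
            alpha=config.alpha,
            family_counts=fam_counts,
            n_boot=config.n_boot,
            seed=seed,
        )
        cls, parent = classify_gene(prop, p_corr, config)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "mat_total": mat,
                "pat_total": pat,
                "mat_proportion": prop,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p_raw": p_raw,
                "p_corr": p_corr,
                "preferred_fraction": max(prop, 1 - prop),
                "locus_class": cls.value,
                "expressed_parent": parent.value,
                "n_informative_families": int(rec.n_informative_families),
            }
        )
    return pd.DataFrame(rows)


def class_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Median preferred-allele fraction per class, biased split by parent.

    Medians use the midpoint convention for even gene counts.  Empty
    classes are omitted.
    """
    rows = []
    for cls in (LocusClass.IMPRINTED, LocusClass.BIASED, LocusClass.BIALLELIC):
        sub = summaries[summaries["locus_class"] == cls.value]
        if sub.empty:
            continue
        rows.append(
            {
                "locus_class": cls.value,
                "expressed_parent": "all",
                "n_genes": len(sub),
                "median_preferred_fraction": float(sub["preferred_fraction"].median()),
            }
        )
        if cls is LocusClass.BIASED:
            for parent in (ExpressedParent.MAT, ExpressedParent.PAT):
                part = sub[sub["expressed_parent"] == parent.value]
                if part.empty:
                    continue
                rows.append(
                    {
                        "locus_class": cls.value,
                        "expressed_parent": parent.value,
                        "n_genes": len(part),
                        "median_preferred_fraction": float(
                            part["preferred_fraction"].median()
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["locus_class", "expressed_parent", "n_genes", "median_preferred_fraction"],
    )


def group_breakdown(
    parental_counts: pd.DataFrame,
    families: Sequence[TrioFamily],
    config: CohortConfig,
) -> pd.DataFrame:
    """Per-gene, per-clinical-group Mat/Pat totals and proportions.

    Groups with zero informative reads for a gene are reported with an
    empty (NaN) proportion, distinguishing "no data" from "proportion 0".
    """
    group_of = {f.family_id: f.clinical_group for f in families}
    counts = parental_counts.assign(
        clinical_group=parental_counts["family_id"].map(group_of)
    )
    genes = sorted(counts["gene_id"].unique())
    rows = []
    for gene in genes:
        sub = counts[counts["gene_id"] == gene]
        for group in CLINICAL_GROUPS:
            part = sub[sub["clinical_group"] == group]
            mat = int(part["mat_reads"].sum())
            pat = int(part["pat_reads"].sum())
            total = mat + pat
            if total > 0:
                prop = mat / total
                ci_low, ci_high = proportion_ci(
                    mat, total, method="clopper_pearson", alpha=config.alpha
                )
            else:
                prop = ci_low = ci_high = float("nan")
            rows.append(
                {
                    "gene_id": gene,
                    "clinical_group": group,
                    "mat_reads": mat,
                    "pat_reads": pat,
                    "mat_proportion": prop,
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "clinical_group", "mat_reads", "pat_reads",
            "mat_proportion", "ci_low", "ci_high",
        ],
    )
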