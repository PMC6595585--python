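# Methods

## The problem

In a placenta, each gene carries one maternally and one paternally
inherited allele.  For most genes both are transcribed (biallelic
expression); for imprinted genes one parental copy is epigenetically
silenced and transcription is (near-)monoallelic.  Given RNA-seq read
counts at exonic SNPs where the placenta is heterozygous, plus genotypes
of the placenta and its parents, one can assign each expressed allele to
a parent and measure the maternal share of transcription gene by gene.
This package implements that analysis end to end for trio (placenta +
mother + father) and duo (placenta + mother) designs, together with a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes.

## Parental-origin assignment

A family is *informative* at a SNP when the placenta is heterozygous and
at least one genotyped parent is homozygous.  The homozygous parent can
only have transmitted its sole allele, which pins the assignment of both
placental alleles.  The decision table in `phasing.classify_family_snp`
covers every genotype combination:

* placenta not heterozygous → uninformative (no allele to distinguish);
* mother homozygous for X → maternal = X, paternal = the other allele;
  if a genotyped father does not carry the paternal allele the call is a
  *Mendelian error* (surfaced as its own status for genotyping-error
  surveillance, never silently dropped);
* mother heterozygous, father homozygous for Y → paternal = Y,
  maternal = the other allele.  This "either parent" reading is the
  package default and can be disabled (`father_hom_informative=False`)
  for a mother-only convention;
* both parents heterozygous, or a duo with a heterozygous mother →
  uninformative;
* a genotype required for the decision is missing → missing_data.

The table is verified in the test suite against a brute-force oracle
that enumerates all transmissions consistent with the parental genotypes
and checks uniqueness of the assignment, over all 36 genotype
combinations.

## Filtering cascade

Candidate genes pass through ordered stages, each recording its dropouts
with exactly one reason (gene sets are strictly nested and counts are
conserved, so the bookkeeping is auditable):

1. **annotation** — a gene needs exon intervals and a count-matrix row;
2. **expression** — median normalized count across samples ≥ 50 reads
   (strictly-below medians drop).  Normalization is median-of-ratios:
   factor_s = median over genes expressed in all samples of
   count_gs / geometric-mean_g;
3. **common exonic SNP** — the gene keeps ≥ 1 SNP that lies in one of
   its exons (BED half-open convention: interval [start, end) covers
   1-based position p iff start < p ≤ end), is not on the manual
   exclusion list, has cohort minor allele frequency strictly above 10%,
   and is in Hardy-Weinberg equilibrium (1-df chi-square p strictly
   above 0.05; monomorphic sites return p = 1 since no departure is
   testable);
4. **informative families** — ≥ 1 SNP informative in ≥ 3 families
   (boundary inclusive);
5. **coverage** — ≥ 1 SNP whose median total reads across informative
   placentas is ≥ 3;
6. **testable** — the gene has ≥ 3 distinct informative families and a
   nonzero read total.

MAF and HWE are computed from the cohort's own genotypes (all genotyped
individuals); an external population frequency table can be applied
upstream by pre-filtering the VCF.  The HWE chi-square test rejects
about 5% of genuinely equilibrated SNPs by construction — a property the
filter-bookkeeping tests account for.

## Gene-level statistics

Maternal (Mat) and paternal (Pat) reads are summed over all informative
families and coverage-passing SNPs of a gene; reads from multiple SNPs
of the same sample are summed without fragment deduplication (a fragment
spanning two SNPs counts twice; an optional per-sample best-SNP mode is
a possible extension, not implemented).  The pooled maternal proportion
θ̂ = Mat / (Mat + Pat) is tested against 0.5 with the exact two-sided
binomial test in the minimum-likelihood convention (sum of probabilities
of all outcomes whose point probability is at most that observed,
relative tolerance 1e-7 — the convention of R's `binom.test`; at p₀ =
0.5 this equals twice the smaller tail, capped at 1).  P-values are
Bonferroni-corrected by m = the number of genes reaching the testing
stage (overridable for re-analyses of a published test set of known
size).

Classification, with f = max(θ̂, 1 − θ̂):

* **imprinted** — corrected p < 0.05 and f > 0.90;
* **biased** — corrected p < 0.05 and 0.65 ≤ f ≤ 0.90;
* **biallelic** — otherwise.

Boundary conventions: "imprinted" requires strictly more than 90% of
reads from one allele, so f = 0.90 falls in the biased band, whose upper
bound is closed to keep the three classes a partition.  Significance
gates the fraction: a skewed f with a non-significant test is biallelic.
The expressed parent is Mat/Pat by the direction of θ̂, "both" for
biallelic genes.

Confidence intervals are reporting-only (classification never uses
them).  Clopper-Pearson is the default; Wilson and a seeded
family-level bootstrap (resampling whole families, the natural
exchangeable unit, and re-pooling) are available because pooled-count
closed forms understate between-family variability.

## Synthetic cohorts

`simulate.generate_cohort` draws, per SNP: parental genotypes at HWE
frequencies (p², 2pq, q²), Mendelian transmission (one allele uniformly
from each parent; duos draw a hidden father so the truth ledger can
score duo rules), and a placental pileup in which each read is
maternal-placental with probability (1 − ρ)θ, paternal-placental with
probability (1 − ρ)(1 − θ), or a maternal-cell contaminant with
probability ρ; contaminant reads follow the mother's own genotype
(which is what decidual contamination does to an allele-specific
signal), and each read flips allele with the sequencing error rate ε.

Defaults and their rationale:

| parameter | default | why |
| --- | --- | --- |
| cohort layout | 38 trios + 16 duos over 7 clinical groups | the reference survey's design (first/second trimester duos; term trios for normal, SGA, LGA, PE, GD) |
| ρ (contamination) | 0.0093 | the published maternal-RNA estimate for this tissue |
| ε (sequencing error) | 0.001 | typical Illumina substitution rate |
| θ per class | 0.98 / 0.02 imprinted, 0.75 / 0.17 biased, 0.5 biallelic | brackets the observed range of class proportions |
| depth per SNP | Poisson, mean 50 | no per-SNP depth distribution is published; only a low-coverage tail is implied, so this is a free parameter |
| SNP MAF | 0.4 | a common variant, keeping informative families frequent |

Depth is Poisson rather than negative-binomial because every statistic
downstream conditions on the total count; overdispersion affects power,
not correctness.  The generator does not emulate: linkage between SNPs
beyond the shared gene θ, isoform-specific imprinting, random
monoallelic expression, alignment or mapping bias, or genotyping error.
Passing recovery tests therefore demonstrate correctness of the
inference given the model, not robustness to those real-data artifacts.

Determinism: all draws come from one `numpy.random.default_rng(seed)`
(PCG64, integer state), so a fixed seed reproduces output files
byte-for-byte across platforms.

## Problem sizes used in the tests

The recovery experiment simulates 200 genes per class (θ = 0.98, 0.83,
0.5) with one common SNP each at sequencing depth 30 in the 54-family
layout — enough for each gene to pool reads from ~15–20 informative
families, the regime the study design targets.  The filter-bookkeeping
fixture uses 50 genes with planted failures of each filter.  Both run in
seconds.

## Reporting

The catalog view standardizes log2(normalized count + 1) expression to
row z-scores (population SD; zero-variance rows are emitted as zeros
with a warning) and orders genes and samples by average-linkage
agglomerative clustering on Minkowski distance (power 2 by default; the
linkage and power are configuration knobs since only the distance is
prescribed by convention).  log2(x + 1) stands in for a
variance-stabilizing transform; the choice is recorded in the output
metadata of the catalog and dominates nothing downstream, since the
z-score step defines the visual scale.  Per-clinical-group breakdowns
are descriptive only — no formal cross-group heterogeneity test is
defined or performed; groups with no informative reads are reported as
empty rather than as proportion zero.

## Known limitations

* Cohort MAF stands in for population MAF when no external frequency
  table is supplied.
* Printed confidence intervals from the reference survey cannot be used
  as validation targets: no closed-form proportion interval reproduces
  all of them, which is why a family-level bootstrap is offered.
* Reads pooled across SNPs double-count multi-SNP fragments (see above).
* The binomial test assumes reads are independent given the gene's θ;
  within-family correlation makes the test anti-conservative for genes
  dominated by few families.
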