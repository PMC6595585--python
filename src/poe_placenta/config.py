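"""Run configuration and core domain types.

No science lives here: these are the validated value objects the rest of
the pipeline passes around.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

#: Clinical subgroups of the cohort, in canonical reporting order:
#: first/second trimester terminations, uncomplicated third trimester,
#: small-/large-for-gestational-age newborn, preeclampsia, gestational
#: diabetes.
CLINICAL_GROUPS: Tuple[str, ...] = (
    "trim1",
    "trim2",
    "trim3_normal",
    "SGA",
    "LGA",
    "PE",
    "GD",
)


class Genotype(enum.IntEnum):
    """Unphased biallelic genotype coded as alternate-allele dosage."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


class CohortConfig(BaseModel):
    """All tunable thresholds of the filtering and classification cascade.

    Defaults reproduce the study conditions of the reference survey:
    common SNPs (MAF > 10%) in Hardy-Weinberg equilibrium (P > 0.05),
    informative in at least 3 families, with at least 3 median reads across
    informative placentas; genes need a median normalized expression of at
    least 50 reads.  A gene is called imprinted when > 90% of reads come
    from one parental allele (and the binomial test is significant after
    Bonferroni correction), parentally biased at 65-90%, biallelic
    otherwise.
    """

    n_tests_bonferroni: Optional[int] = Field(default=None, gt=0)
    min_informative_families: int = Field(default=3, ge=0)
    min_median_reads: int = Field(default=3, ge=0)
    maf_threshold: float = Field(default=0.10, gt=0.0, lt=1.0)
    hwe_alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    expression_median_threshold: float = Field(default=50.0, ge=0.0)
    imprinted_threshold: float = Field(default=0.90, gt=0.0, lt=1.0)
    biased_low: float = Field(default=0.65, gt=0.0, lt=1.0)
    biallelic_band: Tuple[float, float] = (0.35, 0.65)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    ci_method: Literal["clopper_pearson", "wilson", "bootstrap"] = "clopper_pearson"
    n_boot: int = Field(default=2000, gt=0)
    snp_exclusion_list: frozenset[str] = frozenset()
    #: whether a homozygous father can make a mother-het trio informative
    father_hom_informative: bool = True

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_band_order(self) -> "CohortConfig":
        low, high = self.biallelic_band
        if not (0.0 < low < self.biased_low <= self.imprinted_threshold < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < biallelic_band.low < biased_low "
                "<= imprinted_threshold < 1"
            )
        if not (0.0 < low < high < 1.0):
            raise ValueError("biallelic band must be an increasing pair in (0, 1)")
        return self


@dataclass(frozen=True)
class TrioFamily:
    """One pregnancy's sample bundle: placenta, mother, optional father."""

    family_id: str
    placenta_sample: str
    mother_sample: str
    father_sample: Optional[str]
    clinical_group: str
    gestational_age_days: int

    def __post_init__(self) -> None:
        if not self.family_id or not self.placenta_sample or not self.mother_sample:
            raise ValueError("family, placenta and mother identifiers are required")
        if self.clinical_group not in CLINICAL_GROUPS:
            raise ValueError(
                f"unknown clinical group {self.clinical_group!r}; "
                f"expected one of {CLINICAL_GROUPS}"
            )
        if self.gestational_age_days <= 0:
            raise ValueError("gestational age must be a positive number of days")

    @property
    def is_duo(self) -> bool:
        return self.father_sample is None


_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic exonic SNV with its 1-based genomic position."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position is 1-based and must be >= 1")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _NUCLEOTIDES:
                raise ValueError(f"allele {allele!r} is not a single nucleotide")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
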