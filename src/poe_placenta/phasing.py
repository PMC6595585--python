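"""Trio/duo-based assignment of parental origin to placental alleles.

A family is informative at a SNP when the placenta is heterozygous and the
parental genotypes force a unique assignment of its two alleles to mother
and father.  The classic sufficient condition — at least one parent
homozygous — is exactly what makes the assignment unique for unphased
genotypes: the homozygous parent can only have transmitted its sole
allele, so the other placental allele must come from the other parent.

Outcomes are statuses, never exceptions: genotype combinations where no
transmission could produce the placental genotype are flagged as Mendelian
errors (genotyping-error surveillance), and combinations that cannot be
decided because a required genotype is missing are flagged as missing data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import pandas as pd

from poe_placenta.config import CohortConfig, Genotype, TrioFamily


class InformativeStatus(str, enum.Enum):
    INFORMATIVE = "informative"
    UNINFORMATIVE = "uninformative"
    MENDELIAN_ERROR = "mendelian_error"
    MISSING_DATA = "missing_data"


@dataclass(frozen=True)
class InformativeCall:
    """Per (family, SNP) parental-origin decision.

    ``maternal_allele``/``paternal_allele`` are "ref"/"alt" labels, present
    iff the status is informative.
    """

    family_id: str
    snp_id: str
    status: InformativeStatus
    maternal_allele: Optional[str] = None
    paternal_allele: Optional[str] = None

    def __post_init__(self) -> None:
        informative = self.status is InformativeStatus.INFORMATIVE
        has_alleles = self.maternal_allele is not None and self.paternal_allele is not None
        if informative != has_alleles:
            raise ValueError("parental alleles present iff the call is informative")
        if informative and self.maternal_allele == self.paternal_allele:
            raise ValueError("informative call requires distinct parental alleles")


_HOM_ALLELE = {Genotype.HOM_REF: "ref", Genotype.HOM_ALT: "alt"}
_OTHER = {"ref": "alt", "alt": "ref"}


def _carries(gt: Genotype, allele: str) -> bool:
    if gt == Genotype.HET:
        return True
    return _HOM_ALLELE[gt] == allele


def classify_family_snp(
    placenta_gt: Genotype,
    mother_gt: Genotype,
    father_gt: Optional[Genotype],
    *,
    father_hom_informative: bool = True,
) -> Tuple[InformativeStatus, Optional[str], Optional[str]]:
    """Decide informativeness of one family at one SNP.

    ``father_gt`` is ``None`` for a duo (no father sample), as opposed to
    ``Genotype.MISSING`` (father sample present, genotype not called).
    ``father_hom_informative`` toggles whether a homozygous father makes a
    mother-heterozygous trio informative (on by default: either parent
    being homozygous pins the transmission).

    Returns ``(status, maternal_allele, paternal_allele)`` with alleles as
    "ref"/"alt" labels when informative, ``None`` otherwise.
    """
    placenta_gt = Genotype(placenta_gt)
    mother_gt = Genotype(mother_gt)
    if father_gt is not None:
        father_gt = Genotype(father_gt)

    if placenta_gt == Genotype.MISSING:
        return InformativeStatus.MISSING_DATA, None, None
    if placenta_gt != Genotype.HET:
        return InformativeStatus.UNINFORMATIVE, None, None

    # Placenta is het: one ref and one alt allele to attribute.
    if mother_gt in _HOM_ALLELE:
        maternal = _HOM_ALLELE[mother_gt]
        paternal = _OTHER[maternal]
        if father_gt is not None and father_gt != Genotype.MISSING:
            if not _carries(father_gt, paternal):
                return InformativeStatus.MENDELIAN_ERROR, None, None
        return InformativeStatus.INFORMATIVE, maternal, paternal

    if mother_gt == Genotype.HET:
        if father_gt is None:
            return InformativeStatus.UNINFORMATIVE, None, None
        if father_gt == Genotype.MISSING:
            return InformativeStatus.MISSING_DATA, None, None
        if father_gt in _HOM_ALLELE and father_hom_informative:
            paternal = _HOM_ALLELE[father_gt]
            return InformativeStatus.INFORMATIVE, _OTHER[paternal], paternal
        return InformativeStatus.UNINFORMATIVE, None, None

    # Mother genotype missing: a homozygous father can still decide.
    if father_gt is not None and father_gt in _HOM_ALLELE and father_hom_informative:
        paternal = _HOM_ALLELE[father_gt]
        return InformativeStatus.INFORMATIVE, _OTHER[paternal], paternal
    return InformativeStatus.MISSING_DATA, None, None


def call_cohort(
    genotypes: pd.DataFrame,
    families: Sequence[TrioFamily],
    snp_ids: Optional[Sequence[str]] = None,
    *,
    father_hom_informative: bool = True,
) -> pd.DataFrame:
    """Run the decision table over every (family, SNP) pair.

    ``genotypes`` is the samples x SNPs dosage matrix; samples absent from
    it yield missing_data calls.  Returns a DataFrame with columns
    family_id, snp_id, status, maternal_allele, paternal_allele.
    """
    if snp_ids is None:
        snp_ids = list(genotypes.columns)
    rows = []
    for family in families:
        placenta = _sample_row(genotypes, family.placenta_sample)
        mother = _sample_row(genotypes, family.mother_sample)
        father = (
            _sample_row(genotypes, family.father_sample)
            if family.father_sample is not None
            else None
        )
        for snp in snp_ids:
            p = Genotype(int(placenta[snp])) if placenta is not None else Genotype.MISSING
            m = Genotype(int(mother[snp])) if mother is not None else Genotype.MISSING
            f: Optional[Genotype]
            if family.father_sample is None:
                f = None
            elif father is None:
                f = Genotype.MISSING
            else:
                f = Genotype(int(father[snp]))
            status, mat, pat = classify_family_snp(
                p, m, f, father_hom_informative=father_hom_informative
            )
            rows.append(
                {
                    "family_id": family.family_id,
                    "snp_id": snp,
                    "status": status.value,
                    "maternal_allele": mat,
                    "paternal_allele": pat,
                }
            )
    return pd.DataFrame(
        rows, columns=["family_id", "snp_id", "status", "maternal_allele", "paternal_allele"]
    )


def _sample_row(genotypes: pd.DataFrame, sample: str):
    if sample in genotypes.index:
        return genotypes.loc[sample]
    return None


def count_informative_families(calls: pd.DataFrame) -> pd.Series:
    """Number of informative families per SNP (0 for SNPs with no call)."""
    informative = calls[calls["status"] == InformativeStatus.INFORMATIVE.value]
    counts = informative.groupby("snp_id")["family_id"].nunique()
    all_snps = calls["snp_id"].unique()
    return counts.reindex(all_snps, fill_value=0).astype(int)


def informative_snps(calls: pd.DataFrame, config: CohortConfig) -> pd.Index:
    """SNPs informative for at least ``min_informative_families`` families."""
    counts = count_informative_families(calls)
    return counts.index[counts >= config.min_informative_families]
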