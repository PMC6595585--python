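"""The informativeness decision table against an independent enumeration
oracle, plus its symmetry and monotonicity invariants."""

import itertools

import pandas as pd
import pytest

from poe_placenta.config import CohortConfig, Genotype, TrioFamily
from poe_placenta.phasing import (
    InformativeStatus,
    call_cohort,
    classify_family_snp,
    count_informative_families,
    informative_snps,
)

GT3 = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
_ALLELES = {Genotype.HOM_REF: (0,), Genotype.HET: (0, 1), Genotype.HOM_ALT: (1,)}
_LABEL = {0: "ref", 1: "alt"}


def oracle_classify(placenta, mother, father):
    """Brute-force oracle: enumerate every transmission consistent with the
    parental genotypes and check whether the maternal/paternal assignment
    of the het placenta's alleles is unique."""
    if placenta != Genotype.HET:
        return (InformativeStatus.UNINFORMATIVE, None, None)
    paternal_choices = _ALLELES[father] if father is not None else (0, 1)
    assignments = {
        (ma, pa)
        for ma in _ALLELES[mother]
        for pa in paternal_choices
        if {ma, pa} == {0, 1}
    }
    if not assignments:
        return (InformativeStatus.MENDELIAN_ERROR, None, None)
    if len(assignments) == 1:
        ma, pa = assignments.pop()
        return (InformativeStatus.INFORMATIVE, _LABEL[ma], _LABEL[pa])
    return (InformativeStatus.UNINFORMATIVE, None, None)


class TestDecisionTable:
    @pytest.mark.parametrize(
        "placenta,mother,father",
        list(itertools.product(GT3, GT3, GT3 + (None,))),
    )
    def test_matches_enumeration_oracle_on_all_36_combinations(
        self, placenta, mother, father
    ):
        assert classify_family_snp(placenta, mother, father) == oracle_classify(
            placenta, mother, father
        )

    def test_worked_examples(self):
        het, rr, aa = Genotype.HET, Genotype.HOM_REF, Genotype.HOM_ALT
        assert classify_family_snp(het, rr, het) == (
            InformativeStatus.INFORMATIVE, "ref", "alt",
        )
        assert classify_family_snp(het, het, het)[0] == InformativeStatus.UNINFORMATIVE
        # duo with homozygous mother: transmission forced
        assert classify_family_snp(het, aa, None) == (
            InformativeStatus.INFORMATIVE, "alt", "ref",
        )
        # het placenta but neither parent carries alt: impossible transmission
        assert classify_family_snp(het, rr, rr)[0] == InformativeStatus.MENDELIAN_ERROR
        assert classify_family_snp(rr, het, het)[0] == InformativeStatus.UNINFORMATIVE

    def test_missing_genotypes_flagged_not_guessed(self):
        het, miss = Genotype.HET, Genotype.MISSING
        assert classify_family_snp(miss, het, het)[0] == InformativeStatus.MISSING_DATA
        # mother missing but homozygous father still decides
        status, mat, pat = classify_family_snp(het, miss, Genotype.HOM_ALT)
        assert (status, mat, pat) == (InformativeStatus.INFORMATIVE, "ref", "alt")
        # mother het, father genotype not called: cannot decide
        assert classify_family_snp(het, het, miss)[0] == InformativeStatus.MISSING_DATA

    def test_ref_alt_swap_symmetry(self):
        """Relabelling ref<->alt swaps the parental allele labels but never
        changes the status."""
        swap = {
            Genotype.HOM_REF: Genotype.HOM_ALT,
            Genotype.HOM_ALT: Genotype.HOM_REF,
            Genotype.HET: Genotype.HET,
        }
        flip = {"ref": "alt", "alt": "ref", None: None}
        for p, m, f in itertools.product(GT3, GT3, GT3 + (None,)):
            status, mat, pat = classify_family_snp(p, m, f)
            swapped = classify_family_snp(
                swap[p], swap[m], swap[f] if f is not None else None
            )
            assert swapped == (status, flip[mat], flip[pat])

    def test_adding_a_father_never_retracts_informativeness(self):
        """A duo call can only be confirmed or revealed inconsistent by a
        father's genotype, never demoted to uninformative."""
        for p, m in itertools.product(GT3, GT3):
            duo_status = classify_family_snp(p, m, None)[0]
            if duo_status != InformativeStatus.INFORMATIVE:
                continue
            for f in GT3:
                trio_status = classify_family_snp(p, m, f)[0]
                assert trio_status in (
                    InformativeStatus.INFORMATIVE,
                    InformativeStatus.MENDELIAN_ERROR,
                )

    def test_father_hom_rule_is_toggleable(self):
        status, _, _ = classify_family_snp(
            Genotype.HET, Genotype.HET, Genotype.HOM_REF, father_hom_informative=False
        )
        assert status == InformativeStatus.UNINFORMATIVE


class TestCohortCalls:
    def test_truth_ledger_recovered_exactly(self, table1_bundle):
        """On error-free synthetic genotypes every informative call must
        match the simulator's transmitted alleles, with zero Mendelian
        errors."""
        bundle = table1_bundle
        calls = call_cohort(
            bundle.genotype_table.genotypes,
            bundle.families,
            bundle.genotype_table.snps["snp_id"].tolist(),
        )
        assert (calls["status"] == InformativeStatus.MENDELIAN_ERROR.value).sum() == 0
        informative = calls[calls["status"] == InformativeStatus.INFORMATIVE.value]
        merged = informative.merge(
            bundle.truth.phase, on=["family_id", "snp_id"], suffixes=("", "_true")
        )
        assert len(merged) == len(informative)
        assert (merged["maternal_allele"] == merged["maternal_allele_true"]).all()
        assert (merged["paternal_allele"] == merged["paternal_allele_true"]).all()

    def test_informative_family_count_threshold_is_inclusive(self):
        calls = pd.DataFrame(
            {
                "family_id": ["F1", "F2", "F3", "F4"],
                "snp_id": ["s1"] * 3 + ["s2"],
                "status": ["informative"] * 3 + ["uninformative"],
                "maternal_allele": ["ref"] * 3 + [None],
                "paternal_allele": ["alt"] * 3 + [None],
            }
        )
        counts = count_informative_families(calls)
        assert counts["s1"] == 3 and counts["s2"] == 0
        passing = informative_snps(calls, CohortConfig())
        assert list(passing) == ["s1"]  # exactly 3 informative families pass
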