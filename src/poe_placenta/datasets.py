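"""Bundled validation data.

``placental_reference_counts`` is the published gene-level table of
maternal/paternal RNA-seq read counts from a survey of parental allelic
expression across 54 human placentas (trios/duos spanning the three
trimesters and term pregnancy complications).  The survey tested 91 genes
with an exact binomial test and Bonferroni correction over all 91; the
table lists the 25 genes reported as imprinted or parentally biased,
together with the published 2-decimal maternal read proportion, class
label and expressed parental allele.  It serves as a worked example and
as a fixed validation target for the classification pipeline.
"""

from __future__ import annotations

import pandas as pd

#: Bonferroni divisor of the reference survey: one test per analyzed gene.
REFERENCE_N_TESTS = 91

_ROWS = [
    # gene, mat_reads, pat_reads, reported 2-dp maternal proportion,
    # reported class, reported expressed parent
    ("MEG3", 5002, 23, 1.00, "imprinted", "Mat"),
    ("PHLDA2", 154, 5, 0.97, "imprinted", "Mat"),
    ("RTL1", 687, 35, 0.95, "imprinted", "Mat"),
    ("H19", 20522, 1393, 0.94, "imprinted", "Mat"),
    ("PEG10", 13, 6101, 0.00, "imprinted", "Pat"),
    ("IGF2", 52, 6695, 0.01, "imprinted", "Pat"),
    ("MEST", 10, 850, 0.01, "imprinted", "Pat"),
    ("ZFAT", 138, 9652, 0.01, "imprinted", "Pat"),
    ("PLAGL1", 10, 402, 0.02, "imprinted", "Pat"),
    ("DLK1", 50, 1467, 0.03, "imprinted", "Pat"),
    ("AIM1", 65, 971, 0.06, "imprinted", "Pat"),
    ("KLHDC10", 248, 83, 0.75, "biased", "Mat"),
    ("NLRP2", 697, 282, 0.71, "biased", "Mat"),
    ("GRB10", 302, 146, 0.67, "biased", "Mat"),
    ("NAA60", 164, 82, 0.67, "biased", "Mat"),
    ("CPXM2", 72, 588, 0.11, "biased", "Pat"),
    ("MCCC1", 14, 101, 0.12, "biased", "Pat"),
    ("PLEKHG4B", 52, 292, 0.15, "biased", "Pat"),
    ("DCAF10", 15, 78, 0.16, "biased", "Pat"),
    ("DNMT1", 71, 353, 0.17, "biased", "Pat"),
    ("NUDT12", 5, 24, 0.17, "biased", "Pat"),
    ("RHOBTB3", 2264, 10119, 0.18, "biased", "Pat"),
    ("ZDBF2", 226, 878, 0.20, "biased", "Pat"),
    ("MKRN3", 44, 102, 0.30, "biased", "Pat"),
    ("GRHL1", 1825, 3399, 0.35, "biased", "Pat"),
]


def placental_reference_counts() -> pd.DataFrame:
    """The 25-gene reference table of pooled maternal/paternal read counts.

    Columns: gene_id, mat_total, pat_total, reported_proportion (maternal,
    2 decimals), reported_class, reported_parent.
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "gene_id",
            "mat_total",
            "pat_total",
            "reported_proportion",
            "reported_class",
            "reported_parent",
        ],
    )
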