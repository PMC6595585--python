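"""Per-gene catalog, expression standardization and run-level bookkeeping.

The heatmap-style view of expression uses log2(normalized count + 1)
followed by per-gene z-scoring (subtract the mean across samples, divide
by the population standard deviation), and orders genes and samples by
agglomerative clustering on Minkowski distance.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from poe_placenta.config import CLINICAL_GROUPS

logger = logging.getLogger(__name__)


def log_normalized(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), the variance-tempering transform used
    before z-scoring."""
    return np.log2(counts / size_factors + 1.0)


def zscore_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row z-scores: per gene, subtract the mean across samples and divide
    by the standard deviation across samples (population convention).

    Zero-variance rows cannot be standardized; they are emitted as all
    zeros with a warning.
    """
    values = matrix.to_numpy(dtype=np.float64)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=0, keepdims=True)
    flat = (sds == 0).ravel()
    if flat.any():
        logger.warning(
            "%d zero-variance rows standardized to all zeros: %s",
            int(flat.sum()),
            list(matrix.index[flat]),
        )
    safe_sds = np.where(sds == 0, 1.0, sds)
    z = (values - means) / safe_sds
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def hierarchical_order(
    matrix: pd.DataFrame, minkowski_power: float = 2.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Row and column leaf orderings from average-linkage clustering on
    Minkowski distance of the given power."""
    if matrix.shape[0] < 2:
        raise ValueError("clustering requires at least two rows")
    row_link = linkage(
        pdist(matrix.to_numpy(), metric="minkowski", p=minkowski_power), method="average"
    )
    rows = leaves_list(row_link)
    if matrix.shape[1] >= 2:
        col_link = linkage(
            pdist(matrix.to_numpy().T, metric="minkowski", p=minkowski_power),
            method="average",
        )
        cols = leaves_list(col_link)
    else:
        cols = np.arange(matrix.shape[1])
    return rows, cols


def export_catalog(
    summaries: pd.DataFrame,
    groups: pd.DataFrame,
    out_dir,
    class_summaries: Optional[pd.DataFrame] = None,
    expression_stats: Optional[pd.DataFrame] = None,
) -> Dict[str, Path]:
    """Write the per-gene catalog files.

    ``catalog.tsv`` has one row per gene x clinical group (groups in
    canonical order) joined with per-gene overall stats; genes missing
    from ``expression_stats`` get empty expression fields with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["gene_summary"] = out / "gene_summary.tsv"
    summaries.to_csv(paths["gene_summary"], sep="\t", index=False)

    catalog = groups.merge(
        summaries[["gene_id", "locus_class", "expressed_parent", "mat_proportion"]].rename(
            columns={"mat_proportion": "overall_mat_proportion"}
        ),
        on="gene_id",
        how="left",
    )
    if expression_stats is not None:
        missing = set(summaries["gene_id"]) - set(expression_stats.index)
        if missing:
            logger.warning("no expression stats for genes: %s", sorted(missing))
        catalog = catalog.merge(
            expression_stats, left_on="gene_id", right_index=True, how="left"
        )
    order = {g: i for i, g in enumerate(CLINICAL_GROUPS)}
    catalog = catalog.sort_values(
        ["gene_id", "clinical_group"], key=lambda s: s.map(order) if s.name == "clinical_group" else s
    ).reset_index(drop=True)
    paths["catalog"] = out / "catalog.tsv"
    catalog.to_csv(paths["catalog"], sep="\t", index=False)

    if class_summaries is not None:
        paths["class_summary"] = out / "class_summary.tsv"
        class_summaries.to_csv(paths["class_summary"], sep="\t", index=False)

    counts = summaries["locus_class"].value_counts().to_dict()
    logger.info("catalog written: genes per class %s", counts)
    return paths
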