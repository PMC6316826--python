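"""Expression-matrix transforms, clustering, and the DE intersection filter.

FPKM matrices are log10(x+1) transformed before clustering.  K-means (k=2
by default, matching the fiber/ovule grouping) is run with multiple
restarts and a fixed seed; hierarchical clustering (Ward) cuts the tree
into a fixed number of groups (4 for the abiotic-stress profiles).  Group
numbers are canonicalized by descending mean expression so group 1 is
always the most highly expressed.

The differential-expression filter keeps a gene only when |log2FC| > 1 and
FDR < 0.05 in *every* required contrast — e.g. both Verticillium strain
infections — reproducing the two-strain intersection rule.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .io import InputError, PipelineConfig

__all__ = [
    "transform",
    "kmeans_groups",
    "hierarchical_groups",
    "filter_de",
]


def transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log10(FPKM + offset); strictly order-preserving, zero-safe."""
    if (matrix.values < 0).any():
        raise InputError("expression matrix contains negative FPKM values")
    return np.log10(matrix + offset)


def _renumber_by_mean(labels: np.ndarray, matrix: pd.DataFrame) -> pd.Series:
    """Relabel groups 1..k by descending mean expression."""
    means = {
        lab: float(matrix.values[labels == lab].mean())
        for lab in np.unique(labels)
    }
    order = sorted(means, key=lambda l: -means[l])
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    return pd.Series([mapping[l] for l in labels], index=matrix.index,
                     name="group")


def kmeans_groups(
    log_matrix: pd.DataFrame,
    k: int = 2,
    seed: int = 17,
    n_restarts: int = 25,
) -> pd.Series:
    """K-means gene groups (1..k, 1 = highest mean expression)."""
    if k < 1:
        raise InputError("k must be >= 1")
    if k > len(log_matrix):
        raise InputError("k exceeds number of genes")
    if k == 1:
        return pd.Series(1, index=log_matrix.index, name="group")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(log_matrix.values)
    return _renumber_by_mean(labels, log_matrix)


def hierarchical_groups(
    log_matrix: pd.DataFrame,
    n_groups: int = 4,
    linkage: str = "ward",
) -> pd.Series:
    """Ward (default) hierarchical clustering cut into exactly n_groups."""
    if n_groups < 1 or n_groups > len(log_matrix):
        raise InputError("n_groups must be in 1..n_genes")
    if n_groups == len(log_matrix):
        labels = np.arange(len(log_matrix))
    else:
        link = hierarchy.linkage(log_matrix.values, method=linkage)
        labels = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    return _renumber_by_mean(np.asarray(labels), log_matrix)


def filter_de(
    records: pd.DataFrame,
    config: PipelineConfig | None = None,
    require_all_contrasts: bool = True,
    contrasts: Sequence[str] | None = None,
) -> set[str]:
    """Significant DE genes across the required contrasts.

    ``records`` needs columns gene_id / contrast_id / log2fc / fdr.  A gene
    passes one contrast when |log2fc| > de_lfc_min and fdr < de_fdr_max;
    with ``require_all_contrasts`` it must pass every contrast in
    ``contrasts`` (default: all contrasts present in the table), otherwise
    any one suffices.
    """
    config = config or PipelineConfig()
    required = {"gene_id", "contrast_id", "log2fc", "fdr"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"DE table missing columns {sorted(missing)}")
    if ((records["fdr"] < 0) | (records["fdr"] > 1)).any():
        raise InputError("FDR values outside [0, 1]")
    if contrasts is None:
        contrasts = sorted(records["contrast_id"].unique())
    passing = records[
        (records["log2fc"].abs() > config.de_lfc_min)
        & (records["fdr"] < config.de_fdr_max)
        & records["contrast_id"].isin(contrasts)
    ]
    by_gene = passing.groupby("gene_id")["contrast_id"].nunique()
    if require_all_contrasts:
        keep = by_gene[by_gene == len(contrasts)]
    else:
        keep = by_gene[by_gene >= 1]
    return set(keep.index)
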