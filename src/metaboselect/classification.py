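"""Semi-supervised metabolome-based sample labeling.

The class labels used by all downstream statistics are not taken from any
external annotation: samples are projected onto their first principal
components, the score coordinates are clustered hierarchically (Ward.D2 on
Manhattan distances) and the tree is cut into two groups.  The resulting
cluster memberships are the "metabolome-based classification".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import PeakTable
from .stats_core import Dendrogram, cut_dendrogram, hca_ward2, pca_scores

__all__ = ["ClusterAssignment", "assign_metabolome_labels", "compare_labelings",
           "adjusted_rand_index"]

logger = logging.getLogger("metaboselect")


@dataclass
class ClusterAssignment:
    """Per-sample cluster labels plus the dendrogram they came from."""

    labels: pd.Series               # sample_id -> {1, 2, ...}
    consensus_by_cultivar: pd.Series
    dendrogram: Dendrogram
    n_pcs_used: int

    def label_array(self) -> np.ndarray:
        return self.labels.to_numpy()


def _orient_two_clusters(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Number the two clusters so cluster 1 has the higher reference mean.

    The reference is the per-sample grand mean of (log2, unscaled)
    intensities, mirroring the convention that group 1 is the
    higher-abundance group; ties go to the smaller cluster.
    """
    m1 = reference[labels == 1].mean()
    m2 = reference[labels == 2].mean()
    if m1 == m2:  # tie: smaller cluster becomes 1
        swap = (labels == 1).sum() > (labels == 2).sum()
    else:
        swap = m1 < m2
    if swap:
        labels = np.where(labels == 1, 2, 1)
    return labels


def assign_metabolome_labels(table: PeakTable, n_pcs: int = 10, k: int = 2,
                             raw_table: PeakTable | None = None
                             ) -> ClusterAssignment:
    """Cluster samples in principal-component space and cut into k groups.

    PCA scores on the first ``n_pcs`` components (silently capped at what
    the data supports) are clustered by Ward.D2 on Manhattan distances and
    the dendrogram cut at ``k``.  For ``k = 2``, cluster 1 is the cluster
    with the higher grand-mean log2 intensity, computed from ``raw_table``
    when given (the unscaled analysis table), otherwise from the scaled
    table — a deterministic numbering either way.

    Parameters
    ----------
    table
        Analysis-ready (autoscaled, technically averaged) peak table.
    """
    if k > table.n_samples:
        raise ValueError(f"k={k} exceeds the {table.n_samples} samples")
    scores, _, _ = pca_scores(table.values, n_pcs)
    if scores.shape[1] < n_pcs:
        logger.info("n_pcs capped at %d", scores.shape[1])
    dend = hca_ward2(scores, metric="manhattan")
    labels = cut_dendrogram(dend, k)
    if k == 2:
        if raw_table is not None:
            # restrict to the analysis-stage features where possible
            common = [f for f in table.feature_ids
                      if f in set(raw_table.feature_ids)]
            raw = raw_table.subset_features(common) if common else raw_table
            aligned = raw.values[raw.sample_ids.get_indexer(table.sample_ids)]
            reference = np.log2(np.maximum(aligned, np.finfo(float).tiny)
                                ).mean(axis=1)
        else:
            reference = table.values.mean(axis=1)
        labels = _orient_two_clusters(labels, reference)
    label_series = pd.Series(labels, index=table.sample_ids, name="cluster")
    cultivars = table.samples["cultivar"]
    consensus = (
        label_series.groupby(cultivars)
        .agg(lambda s: int(s.value_counts().idxmax()))
        .rename("cluster")
    )
    return ClusterAssignment(
        labels=label_series, consensus_by_cultivar=consensus,
        dendrogram=dend, n_pcs_used=int(scores.shape[1]),
    )


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two partitions of the same samples."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("labelings differ in length")
    n = len(a)
    cats_a, inv_a = np.unique(a, return_inverse=True)
    cats_b, inv_b = np.unique(b, return_inverse=True)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    np.add.at(table, (inv_a, inv_b), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(table).sum()
    sum_rows = comb2(table.sum(axis=1)).sum()
    sum_cols = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total if total > 0 else 0.0
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def compare_labelings(a, b) -> dict:
    """Quantitative agreement between two labelings of the same samples.

    Returns the adjusted Rand index (1 iff the partitions coincide, ≈ 0
    for independent labelings) and the cross-tabulation.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("labelings differ in length")
    crosstab = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    return {"ari": adjusted_rand_index(a, b), "crosstab": crosstab}
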