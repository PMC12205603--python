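"""Hierarchical clustering of cases and differential protein abundance.

Cases are clustered on binary phosphosite-presence profiles (Ward linkage,
Euclidean distance) or on standardized log2 protein abundances; the merge
history is kept as a :class:`LinkageTree` supporting k-cuts and Newick
export.  Protein-level group comparisons use the mean log2 precursor
abundance per group with an unpaired two-sided t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

log = logging.getLogger(__name__)

LINKAGE_METHODS = ("ward", "average")


@dataclass
class LinkageTree:
    """Agglomerative merge history.

    ``merges`` follows the scipy linkage convention: row k merges clusters
    ``merges[k, 0]`` and ``merges[k, 1]`` (indices < n are leaves, index
    n + j is the cluster formed at merge j) at height ``merges[k, 2]`` into
    a cluster of size ``merges[k, 3]``.
    """

    merges: np.ndarray
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into k clusters by undoing the last k-1 merges."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}, got {k}")
        flat = sch.cut_tree(self.merges, n_clusters=k).ravel()
        return {label: int(c) for label, c in zip(self.leaf_labels, flat)}

    def leaf_order(self) -> list[str]:
        """Leaves in dendrogram display order."""
        order = sch.leaves_list(self.merges)
        return [self.leaf_labels[i] for i in order]


def hierarchical_cluster(
    matrix: pd.DataFrame, method: str = "ward", metric: str = "euclidean"
) -> LinkageTree:
    """Agglomerative clustering of the matrix rows.

    Ward linkage minimizes the within-cluster variance increase at each
    merge; average linkage (UPGMA) merges by mean pairwise distance.
    Missing values are rejected — the caller decides the imputation policy
    (the differential-expression heatmap path imputes zero).
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}, got {method!r}")
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if np.isnan(values).any():
        raise ValueError(
            "matrix contains missing values; impute before clustering "
            "(e.g. zero for merged log2 fold changes)"
        )
    merges = sch.linkage(values, method=method, metric=metric)
    return LinkageTree(merges=merges, leaf_labels=[str(i) for i in matrix.index])


def cluster_from_dissimilarity(diss: np.ndarray, method: str = "average") -> np.ndarray:
    """Linkage matrix from a square dissimilarity matrix."""
    from scipy.spatial.distance import squareform

    return sch.linkage(squareform(diss, checks=False), method=method)


def top_n_union(abundance: pd.DataFrame, n: int) -> list[str]:
    """Union of each case's top-n most abundant proteins.

    Per case, proteins rank by abundance descending with ties broken by
    identifier; missing values never enter a case's ranking.  Mirrors the
    "top 20 per sample, combined" selection used for the most abundant
    proteins of the sarkosyl-insoluble fraction.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    selected: set[str] = set()
    for case in abundance.columns:
        col = abundance[case].dropna()
        ranked = sorted(col.items(), key=lambda kv: (-kv[1], str(kv[0])))
        selected.update(str(p) for p, _ in ranked[:n])
    return sorted(selected)


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores (population standard deviation, ddof=0)."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    zero = sd.ravel() == 0
    if zero.any():
        name = matrix.index[int(np.argmax(zero))]
        raise ValueError(f"constant row cannot be standardized: {name!r}")
    return pd.DataFrame(
        (values - mean) / sd, index=matrix.index, columns=matrix.columns
    )


def group_differential(
    abundance: pd.DataFrame,
    groups: dict[str, str],
    case_group: str,
    control_group: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein group comparison of mean log2 abundance.

    Returns mean log2 abundance per group, the log2 fold change
    (case - control), the unpaired t statistic and two-sided p-value,
    ranked by p ascending (ties by protein id).  Proteins with fewer than
    two non-missing values in either group are skipped and logged.
    """
    case_cols = [c for c in abundance.columns if groups.get(c) == case_group]
    ctrl_cols = [c for c in abundance.columns if groups.get(c) == control_group]
    rows = []
    for protein, values in abundance.iterrows():
        a = values[case_cols].dropna().to_numpy(dtype=float)
        b = values[ctrl_cols].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            log.info("skipping %s: fewer than 2 values in a group", protein)
            continue
        lfc = a.mean() - b.mean()
        if np.ptp(a) == 0 and np.ptp(b) == 0 and lfc == 0:
            t, p = 0.0, 1.0  # identical constant groups
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "protein": str(protein),
                f"mean_{case_group}": a.mean(),
                f"mean_{control_group}": b.mean(),
                "log2fc": lfc,
                "t": float(t),
                "pvalue": float(p),
            }
        )
    result = pd.DataFrame(rows)
    if not result.empty:
        result = result.sort_values(
            ["pvalue", "protein"], kind="mergesort"
        ).reset_index(drop=True)
    return result
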