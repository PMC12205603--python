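"""Concordance analysis of per-condition differential-expression tables.

Implements the post-processing applied to vendor-called DEG tables:
significance filtering at adjusted p < 0.05, Venn-style overlap with
direction split and fold-change correlation of shared genes, pairwise and
within-group mean Jaccard similarity of significant gene sets, the
top-DEG ranking (lowest p, |log2FC| above a floor), and the zero-imputed
log2-fold-change matrix behind the clustered DEG heatmap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import hierarchical_cluster

log = logging.getLogger(__name__)


@dataclass
class DEGSet:
    """Significant genes of one condition with their regulation direction."""

    condition: str
    genes: frozenset[str]
    direction: dict[str, str]  # gene -> "up" | "down"

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.direction.values() if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.direction.values() if d == "down")

    @property
    def up_genes(self) -> frozenset[str]:
        return frozenset(g for g, d in self.direction.items() if d == "up")

    @property
    def down_genes(self) -> frozenset[str]:
        return frozenset(g for g, d in self.direction.items() if d == "down")


def filter_deg(
    table: pd.DataFrame,
    condition: str = "",
    alpha: float = 0.05,
    p_column: str = "padj",
) -> DEGSet:
    """Genes with adjusted p strictly below alpha.

    Rows with a missing p-value are excluded (and logged); genes with a
    log2 fold change of exactly zero stay in the set but carry no
    direction.  ``p_column="pvalue"`` switches to raw-p filtering.
    """
    n_missing = int(table[p_column].isna().sum())
    if n_missing:
        log.info("%s: %d rows without %s excluded", condition or "table", n_missing, p_column)
    sig = table.loc[table[p_column] < alpha]
    direction = {}
    for gene, lfc in zip(sig["gene_id"], sig["log2fc"]):
        if lfc > 0:
            direction[str(gene)] = "up"
        elif lfc < 0:
            direction[str(gene)] = "down"
        else:
            log.info("%s: gene %s significant with zero fold change", condition, gene)
    return DEGSet(
        condition=condition,
        genes=frozenset(str(g) for g in sig["gene_id"]),
        direction=direction,
    )


def jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    """|A intersect B| / |A union B|; two empty sets give 0 with a warning."""
    union = set(a) | set(b)
    if not union:
        log.warning("Jaccard of two empty sets; returning 0")
        return 0.0
    return len(set(a) & set(b)) / len(union)


def pairwise_jaccard(sets: dict[str, DEGSet]) -> pd.DataFrame:
    names = list(sets)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            j = jaccard(sets[a].genes, sets[b].genes)
            out.loc[a, b] = out.loc[b, a] = j
    return out


def group_mean_jaccard(
    sets: dict[str, DEGSet],
    group_of_condition: dict[str, str],
    split_direction: bool = False,
) -> dict[str, float]:
    """Mean pairwise Jaccard over unordered within-group condition pairs.

    With ``split_direction=True`` each pair's similarity is the mean of the
    Jaccard indices of the up-regulated and down-regulated subsets instead
    of the combined significant sets.
    """
    groups: dict[str, list[str]] = {}
    for cond in sets:
        groups.setdefault(group_of_condition[cond], []).append(cond)

    def pair_j(a: DEGSet, b: DEGSet) -> float:
        if split_direction:
            return (jaccard(a.up_genes, b.up_genes) + jaccard(a.down_genes, b.down_genes)) / 2
        return jaccard(a.genes, b.genes)

    out = {}
    for g, conds in groups.items():
        if len(conds) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 conditions")
        vals = [
            pair_j(sets[a], sets[b])
            for i, a in enumerate(conds)
            for b in conds[i + 1 :]
        ]
        out[g] = float(np.mean(vals))
    return out


@dataclass
class OverlapResult:
    """Venn counts and shared-gene fold-change concordance of two conditions."""

    unique_a: int
    unique_b: int
    shared: int
    unique_a_up: int
    unique_a_down: int
    unique_b_up: int
    unique_b_down: int
    shared_lfc: pd.DataFrame  # gene, log2fc_a, log2fc_b
    pearson_r: float | None


def overlap_analysis(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapResult:
    """Overlap of two conditions' significant sets with fold-change correlation.

    The Pearson correlation over shared genes' (log2FC_A, log2FC_B) pairs
    needs at least 3 shared genes; otherwise it is reported missing.
    """
    set_a = filter_deg(table_a, name_a, alpha)
    set_b = filter_deg(table_b, name_b, alpha)
    shared = set_a.genes & set_b.genes
    only_a = set_a.genes - shared
    only_b = set_b.genes - shared

    lfc_a = table_a.set_index("gene_id")["log2fc"]
    lfc_b = table_b.set_index("gene_id")["log2fc"]
    shared_sorted = sorted(shared)
    shared_lfc = pd.DataFrame(
        {
            "gene_id": shared_sorted,
            "log2fc_a": [float(lfc_a[g]) for g in shared_sorted],
            "log2fc_b": [float(lfc_b[g]) for g in shared_sorted],
        }
    )
    if len(shared_sorted) >= 3:
        r = float(stats.pearsonr(shared_lfc["log2fc_a"], shared_lfc["log2fc_b"])[0])
    else:
        r = None
    return OverlapResult(
        unique_a=len(only_a),
        unique_b=len(only_b),
        shared=len(shared),
        unique_a_up=sum(1 for g in only_a if set_a.direction.get(g) == "up"),
        unique_a_down=sum(1 for g in only_a if set_a.direction.get(g) == "down"),
        unique_b_up=sum(1 for g in only_b if set_b.direction.get(g) == "up"),
        unique_b_down=sum(1 for g in only_b if set_b.direction.get(g) == "down"),
        shared_lfc=shared_lfc,
        pearson_r=r,
    )


def top_deg_table(
    table: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.5, n: int = 25
) -> pd.DataFrame:
    """Top-n significant genes with |log2FC| above the floor, by smallest p.

    Ties in p-value break lexicographically by gene id.
    """
    mask = (table["padj"] < alpha) & (table["log2fc"].abs() > lfc_min)
    qualifying = table.loc[mask].copy()
    qualifying = qualifying.sort_values(
        ["pvalue", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    return qualifying.head(n)


def deg_heatmap_matrix(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05, cluster: bool = True
) -> pd.DataFrame:
    """Merged log2FC matrix over every gene significant somewhere.

    Cells hold the condition's log2 fold change where the gene is
    significant there, and 0 otherwise (no change relative to untreated).
    With ``cluster=True``, rows and columns are ordered by average-linkage
    Euclidean clustering of the imputed matrix.
    """
    if not tables:
        raise ValueError("need at least one DEG table")
    sets = {cond: filter_deg(t, cond, alpha) for cond, t in tables.items()}
    genes = sorted(set().union(*(s.genes for s in sets.values())))
    conditions = list(tables)
    matrix = pd.DataFrame(0.0, index=genes, columns=conditions)
    for cond, table in tables.items():
        lfc = table.set_index("gene_id")["log2fc"]
        for g in sets[cond].genes:
            matrix.loc[g, cond] = float(lfc[g])
    if cluster and len(genes) >= 2:
        row_order = hierarchical_cluster(matrix, method="average").leaf_order()
        matrix = matrix.loc[row_order]
        if len(conditions) >= 2:
            col_order = hierarchical_cluster(matrix.T, method="average").leaf_order()
            matrix = matrix[col_order]
    return matrix
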