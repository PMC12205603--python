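"""Weighted co-expression module analysis.

A light-weight re-creation of the standard weighted-network workflow:
Pearson correlation between genes, soft thresholding at the smallest power
giving an approximately scale-free degree distribution, topological
overlap, average-linkage clustering with a static height cut, module
eigengenes (first principal component of a module's standardized
expression), module selection by uniformity of eigengene values across
technical replicates, and hub genes by eigengene correlation (kME) plus
intramodular connectivity.

A deliberate simplification: module detection uses a static cut at a high
quantile of the merge heights with a minimum module size, not the dynamic
hybrid tree cut of the reference R implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class NetworkParams:
    """Chosen soft-threshold power with the scale-free fit diagnostics."""

    beta: int
    signed: bool
    fit_r2: dict[int, float] = field(default_factory=dict)
    mean_connectivity: dict[int, float] = field(default_factory=dict)


@dataclass
class ModuleAssignment:
    """Gene-to-module labels with per-module summaries."""

    labels: dict[str, str]
    eigengenes: pd.DataFrame | None = None  # modules x samples, unit norm rows
    uniformity: dict[str, float] = field(default_factory=dict)
    selected: set[str] = field(default_factory=set)
    hubs: dict[str, list[str]] = field(default_factory=dict)

    def modules(self) -> list[str]:
        return sorted({m for m in self.labels.values() if m != UNASSIGNED})

    def genes_of(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]


def _drop_constant_genes(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        log.warning("removing %d constant gene(s) before correlation", int(constant.sum()))
        expr = expr.loc[~constant]
    return expr


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation of a genes x samples matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(expr.to_numpy(dtype=float))
    return np.clip(corr, -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) against log10 k over equal-count degree bins.

    Scale-free topology means the degree distribution follows a power law:
    the log-log plot of degree density against degree is close to linear.
    Equal-count (quantile) bins keep every bin populated; the probability
    density of a bin is its occupancy fraction divided by its width.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    n_bins = max(5, min(n_bins, k.size // 2))
    if np.unique(k).size < 2 or k.size < n_bins:
        return 0.0
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 4:
        return 0.0
    edges[-1] = np.nextafter(edges[-1], np.inf)
    counts, edges = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    mask = (counts > 0) & (widths > 0)
    if mask.sum() < 3:
        return 0.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / counts.sum() / widths
    x = np.log10(centers[mask])
    y = np.log10(density[mask])
    if np.unique(x).size < 2:
        return 0.0
    fit = stats.linregress(x, y)
    return float(fit.rvalue) ** 2


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=range(1, 21),
    r2_target: float = 0.8,
    signed: bool = False,
) -> NetworkParams:
    """Smallest power whose connectivity distribution fits scale-free topology.

    For each candidate power, connectivity is k_i = sum_j |cor(i, j)|^beta;
    the fit is the R^2 of the binned log-log degree distribution.  If no
    power reaches the target R^2, the best-fitting one is chosen.
    """
    expr = _drop_constant_genes(expr)
    if expr.shape[0] < 30:
        log.warning("only %d genes; soft-threshold fit may be unstable", expr.shape[0])
    corr = correlation_matrix(expr)
    abs_corr = np.abs(corr)
    np.fill_diagonal(abs_corr, 0.0)
    if np.allclose(abs_corr[~np.eye(len(abs_corr), dtype=bool)], 1.0):
        log.warning("all genes perfectly correlated; degree distribution degenerate")
    fit_r2, mean_k = {}, {}
    for beta in powers:
        k = (abs_corr**beta).sum(axis=1)
        fit_r2[beta] = scale_free_fit(k)
        mean_k[beta] = float(k.mean())
    passing = [b for b in powers if fit_r2[b] >= r2_target]
    beta = passing[0] if passing else max(powers, key=lambda b: (fit_r2[b], -b))
    return NetworkParams(beta=int(beta), signed=signed, fit_r2=fit_r2, mean_connectivity=mean_k)


def adjacency(expr: pd.DataFrame, params: NetworkParams) -> np.ndarray:
    """Weighted adjacency a_ij = |cor|^beta (unsigned) with zero diagonal.

    The signed variant uses ((1 + cor) / 2)^beta, mapping negative
    correlations toward zero instead of folding them in.
    """
    corr = correlation_matrix(expr)
    if params.signed:
        a = ((1.0 + corr) / 2.0) ** params.beta
    else:
        a = np.abs(corr) ** params.beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity 1 - TOM, in [0, 1].

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    crediting shared neighbourhoods on top of the direct connection.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any():
        raise ValueError("adjacency must be nonnegative")
    if np.abs(np.diag(a)).max(initial=0.0) != 0:
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    return np.clip(diss, 0.0, 1.0)


def detect_modules(
    diss: np.ndarray,
    genes: list[str],
    min_module_size: int = 10,
    cut_quantile: float = 0.99,
) -> ModuleAssignment:
    """Average-linkage tree on the dissimilarity, cut at a height quantile.

    Clusters below ``min_module_size`` become unassigned.  Modules are
    labeled M1, M2, ... in decreasing size order (ties by first gene), so
    labels are deterministic for a fixed input.
    """
    n = len(genes)
    if n < min_module_size:
        log.warning("fewer genes (%d) than min_module_size (%d)", n, min_module_size)
        return ModuleAssignment(labels={g: UNASSIGNED for g in genes})
    merges = sch.linkage(squareform(diss, checks=False), method="average")
    threshold = float(np.quantile(merges[:, 2], cut_quantile))
    flat = sch.fcluster(merges, t=threshold, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for idx, c in enumerate(flat):
        clusters.setdefault(int(c), []).append(idx)
    keep = [m for m in clusters.values() if len(m) >= min_module_size]
    keep.sort(key=lambda m: (-len(m), m[0]))
    labels = {g: UNASSIGNED for g in genes}
    for mi, members in enumerate(keep):
        for idx in members:
            labels[genes[idx]] = f"M{mi + 1}"
    if not keep:
        log.warning("no cluster reached min_module_size=%d; all genes unassigned", min_module_size)
    return ModuleAssignment(labels=labels)


def module_eigengene(expr: pd.DataFrame, module_genes: list[str]) -> pd.Series:
    """First principal component of the gene-standardized module submatrix.

    Unit norm across samples; the sign is fixed so the eigengene correlates
    non-negatively with the module's mean standardized expression profile.
    """
    if len(module_genes) < 2:
        raise ValueError("module eigengene needs at least 2 genes")
    sub = expr.loc[module_genes].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    # samples x genes SVD: first left singular vector spans the samples
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    eigengene = u[:, 0]
    reference = z.mean(axis=0)
    if np.dot(eigengene, reference) < 0:
        eigengene = -eigengene
    return pd.Series(eigengene, index=expr.columns, name="eigengene")


def select_uniform_modules(
    assignment: ModuleAssignment,
    replicate_map: dict[str, tuple[str, int]],
    sd_threshold: float = 0.5,
) -> ModuleAssignment:
    """Flag modules whose eigengene is consistent across technical replicates.

    The uniformity score of a module is the mean over conditions of the
    population standard deviation of its eigengene across that condition's
    replicates; modules scoring <= threshold are selected.  Requires every
    condition to carry at least 2 replicates.  Note the eigengene has unit
    norm across samples, so scores shrink as the number of samples grows;
    the threshold is interpreted on that scale.
    """
    if assignment.eigengenes is None:
        raise ValueError("assignment carries no eigengenes; compute them first")
    by_condition: dict[str, list[str]] = {}
    for sample, (cond, _r) in replicate_map.items():
        by_condition.setdefault(cond, []).append(sample)
    for cond, samples in by_condition.items():
        if len(samples) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
    assignment.uniformity = {}
    assignment.selected = set()
    for module, profile in assignment.eigengenes.iterrows():
        sds = [
            float(np.std([profile[s] for s in samples], ddof=0))
            for samples in by_condition.values()
        ]
        score = float(np.mean(sds))
        assignment.uniformity[module] = score
        if score <= sd_threshold:
            assignment.selected.add(module)
    return assignment


def hub_genes(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    adj: np.ndarray,
    genes: list[str],
    kme_threshold: float = 0.8,
    connectivity_quantile: float = 0.9,
) -> dict[str, list[str]]:
    """Per-module hub genes: high kME and top-decile intramodular connectivity.

    kME is the correlation of a gene's expression with its module
    eigengene; intramodular connectivity is the gene's adjacency row-sum
    restricted to its module.  Hubs are ranked by kME descending.
    """
    index_of = {g: i for i, g in enumerate(genes)}
    hubs: dict[str, list[str]] = {}
    for module in assignment.modules():
        members = assignment.genes_of(module)
        if not members:
            raise ValueError(f"module {module!r} is empty")
        eigengene = (
            assignment.eigengenes.loc[module]
            if assignment.eigengenes is not None
            else module_eigengene(expr, members)
        )
        idx = [index_of[g] for g in members]
        sub_adj = adj[np.ix_(idx, idx)]
        connectivity = sub_adj.sum(axis=1)
        cutoff = np.quantile(connectivity, connectivity_quantile)
        kme = {}
        for g in members:
            vals = expr.loc[g].to_numpy(dtype=float)
            if np.std(vals) == 0 or np.std(eigengene.to_numpy()) == 0:
                kme[g] = 0.0
            else:
                kme[g] = abs(float(np.corrcoef(vals, eigengene.to_numpy())[0, 1]))
        selected = [
            g
            for g, ki in zip(members, connectivity)
            if kme[g] >= kme_threshold and ki >= cutoff
        ]
        hubs[module] = sorted(selected, key=lambda g: (-kme[g], g))
    assignment.hubs = hubs
    return hubs


def coexpression_pipeline(
    expr: pd.DataFrame,
    replicate_map: dict[str, tuple[str, int]] | None = None,
    beta: int | None = None,
    signed: bool = False,
    min_module_size: int = 10,
    cut_quantile: float = 0.99,
    sd_threshold: float = 0.5,
    kme_threshold: float = 0.8,
) -> tuple[ModuleAssignment, NetworkParams]:
    """Full workflow: power selection, adjacency, TOM, modules, eigengenes,
    replicate-uniformity selection, hub genes."""
    expr = _drop_constant_genes(expr)
    if beta is None:
        params = pick_soft_threshold(expr, signed=signed)
    else:
        params = NetworkParams(beta=int(beta), signed=signed)
    adj = adjacency(expr, params)
    diss = tom_dissimilarity(adj)
    genes = [str(g) for g in expr.index]
    assignment = detect_modules(diss, genes, min_module_size, cut_quantile)
    modules = assignment.modules()
    if modules:
        eig = pd.DataFrame(
            {m: module_eigengene(expr, assignment.genes_of(m)) for m in modules}
        ).T
        eig.index.name = "module"
        assignment.eigengenes = eig
        if replicate_map is not None:
            select_uniform_modules(assignment, replicate_map, sd_threshold)
        hub_genes(expr, assignment, adj, genes, kme_threshold)
    return assignment, params
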