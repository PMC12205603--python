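"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the data the pipeline consumes, at the scale of the
study they model: nine brain-derived cases (six disease, three control),
peptide-level precursor abundances over tryptic tau peptides with planted
per-site phospho-occupancy, binary site-presence matrices with a planted
three-group case structure, per-condition differential-expression tables
with a planted within-group Jaccard overlap and fold-change correlation,
and expression matrices with planted co-expression modules observed over
conditions with technical replicates.

Every generator is a pure function of its configuration and seed: the same
inputs give byte-identical outputs, and no global random state is touched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sites import SiteKey, tryptic_peptides

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generators.

    Defaults mirror the modeled study: 9 cases in 3 groups, ~20 quantified
    phosphosites, log-normal precursor abundances around 1e6 intensity
    units, a 5% bit-flip rate on binary presence profiles, within-group DEG
    Jaccard 0.33, shared-gene fold-change correlation 0.99, and three
    50-gene co-expression modules at latent correlation 0.8 over 9
    conditions with 3 technical replicates each.
    """

    seed: int = 0
    n_cases: int = 9
    n_sites: int = 20
    n_genes: int = 2000
    n_conditions: int = 9
    n_replicates: int = 3
    flip_rate: float = 0.05
    prototype_min_separation: int = 10
    abundance_log_mean: float = math.log(1e6)
    abundance_log_sd: float = 1.0
    noise_log_sd: float = 0.15
    min_peptide_length: int = 6
    target_jaccard: float = 0.33
    target_lfc_correlation: float = 0.99
    deg_set_size: int = 100
    lfc_sd: float = 2.0
    alpha: float = 0.05
    replicate_noise_sd: float = 0.1
    module_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(50, 0.8), (50, 0.8), (50, 0.8)]
    )

    def __post_init__(self):
        for name in ("n_cases", "n_sites", "n_genes", "n_conditions", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("flip_rate", "target_jaccard", "alpha"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1 <= self.target_lfc_correlation <= 1:
            raise ValueError("target_lfc_correlation must lie in [-1, 1]")
        for size, corr in self.module_spec:
            if size < 2 or not 0 < corr <= 1:
                raise ValueError(
                    "module_spec entries must be (size >= 2, latent correlation in (0, 1])"
                )

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


DEFAULT_GROUPS = ("Ctr", "AD-seeding", "AD-nonseeding")


def default_case_labels(n_cases: int) -> list[str]:
    return [f"case{i + 1}" for i in range(n_cases)]


def assign_groups(cases: list[str], groups=DEFAULT_GROUPS) -> dict[str, str]:
    """Deterministic contiguous partition of cases into the given groups."""
    n = len(cases)
    base, extra = divmod(n, len(groups))
    out, start = {}, 0
    for gi, g in enumerate(groups):
        size = base + (1 if gi < extra else 0)
        for case in cases[start : start + size]:
            out[case] = g
        start += size
    return out


@dataclass
class OccupancyTruth:
    """Planted fractional phospho-occupancy per case and canonical site."""

    sites: list[SiteKey]
    occupancy: np.ndarray  # cases x sites, entries in [0, 1]
    cases: list[str]
    group_of_case: dict[str, str]

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (len(self.cases), len(self.sites)):
            raise ValueError("occupancy must be cases x sites")
        if ((occ < 0) | (occ > 1)).any():
            raise ValueError("occupancy entries must lie in [0, 1]")
        self.occupancy = occ


def coverable_sites(sequence: str, min_peptide_length: int = 6) -> list[SiteKey]:
    """S/T/Y positions lying inside tryptic peptides long enough to be observed."""
    out = []
    for start, pep in tryptic_peptides(sequence):
        if len(pep) < min_peptide_length:
            continue
        for k, aa in enumerate(pep):
            if aa in "STY":
                out.append(SiteKey(aa, start + k))
    return out


def make_occupancy_truth(cfg: SimulationConfig, sequence: str) -> OccupancyTruth:
    """Random occupancy truth over detectable sites of the given isoform.

    At most one site is planted per tryptic peptide: the modified/unmodified
    ratio of a peptide carrying several occupied sites confounds each site's
    occupancy with its neighbours', so distinct peptides keep the planted
    occupancy identifiable from the ratios.
    """
    rng = cfg.rng(salt=101)
    by_peptide: dict[int, list[SiteKey]] = {}
    for start, pep in tryptic_peptides(sequence):
        if len(pep) < cfg.min_peptide_length:
            continue
        sites = [SiteKey(aa, start + k) for k, aa in enumerate(pep) if aa in "STY"]
        if sites:
            by_peptide[start] = sites
    if cfg.n_sites > len(by_peptide):
        raise ValueError(
            f"requested {cfg.n_sites} sites but only {len(by_peptide)} detectable "
            "peptides carry S/T/Y residues"
        )
    starts = sorted(by_peptide)
    picked = rng.choice(len(starts), size=cfg.n_sites, replace=False)
    chosen = sorted(
        by_peptide[starts[i]][rng.integers(len(by_peptide[starts[i]]))] for i in picked
    )
    occupancy = rng.uniform(0.05, 0.95, size=(cfg.n_cases, cfg.n_sites))
    cases = default_case_labels(cfg.n_cases)
    return OccupancyTruth(
        sites=chosen,
        occupancy=occupancy,
        cases=cases,
        group_of_case=assign_groups(cases),
    )


def simulate_psm_table(
    truth: OccupancyTruth, sequence: str, cfg: SimulationConfig
) -> pd.DataFrame:
    """Peptide-level precursor abundances realizing the planted occupancy.

    Each tryptic peptide of each case draws a log-normal total abundance.
    For every planted site the peptide covers, a singly phosphorylated row
    carries the fraction of the total equal to the site's occupancy; the
    unmodified row carries the product of the sites' non-occupancy.  Row
    intensities get independent multiplicative log-normal noise with unit
    mean, so expected fractions equal the planted occupancies exactly.
    """
    peptides = [
        (start, pep)
        for start, pep in tryptic_peptides(sequence)
        if len(pep) >= cfg.min_peptide_length
    ]
    site_index = {s: j for j, s in enumerate(truth.sites)}
    covered: set[SiteKey] = set()
    for start, pep in peptides:
        for k, aa in enumerate(pep):
            key = SiteKey(aa, start + k) if aa in "STY" else None
            if key is not None and key in site_index:
                covered.add(key)
    uncovered = [s for s in truth.sites if s not in covered]
    if uncovered:
        raise ValueError(
            "site(s) not covered by any detectable tryptic peptide: "
            + ", ".join(str(s) for s in uncovered)
        )

    rng = cfg.rng(salt=202)
    sigma = cfg.noise_log_sd

    def noisy(value: float) -> float:
        if sigma == 0:
            return value
        return value * math.exp(rng.normal(-0.5 * sigma**2, sigma))

    rows = []
    for ci, case in enumerate(truth.cases):
        for start, pep in peptides:
            total = float(
                rng.lognormal(mean=cfg.abundance_log_mean, sigma=cfg.abundance_log_sd)
            )
            local_sites = [
                (k + 1, site_index[SiteKey(aa, start + k)])
                for k, aa in enumerate(pep)
                if aa in "STY" and SiteKey(aa, start + k) in site_index
            ]
            unmod_fraction = 1.0
            for offset, sj in local_sites:
                theta = truth.occupancy[ci, sj]
                unmod_fraction *= 1.0 - theta
                if theta > 0:
                    rows.append(
                        {
                            "sample_id": case,
                            "peptide": pep,
                            "phospho_offsets": (offset,),
                            "precursor_abundance": noisy(total * theta),
                        }
                    )
            if unmod_fraction > 0:
                rows.append(
                    {
                        "sample_id": case,
                        "peptide": pep,
                        "phospho_offsets": (),
                        "precursor_abundance": noisy(total * unmod_fraction),
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "peptide", "phospho_offsets", "precursor_abundance"]
    )


# ---------------------------------------------------------------------------
# Binary presence/absence matrices with planted case groups


def simulate_binary_ptm(
    cfg: SimulationConfig, groups=DEFAULT_GROUPS
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Binary site-presence matrix with a planted group structure.

    Each group gets a prototype presence vector; prototypes are redrawn
    until all pairwise Hamming distances reach the configured separation.
    Each case's row is its group's prototype with independent bit flips at
    ``flip_rate``.  Returns (matrix, case -> group, prototypes).
    """
    rng = cfg.rng(salt=303)
    n_groups = len(groups)
    expected_flips = cfg.flip_rate * cfg.n_sites
    if cfg.prototype_min_separation < 2 * expected_flips:
        log.warning(
            "prototype separation %d below twice the expected flips (%.2f); "
            "group recovery is not guaranteed",
            cfg.prototype_min_separation,
            expected_flips,
        )
    for _ in range(10_000):
        protos = rng.integers(0, 2, size=(n_groups, cfg.n_sites))
        dists = [
            int(np.sum(protos[a] != protos[b]))
            for a in range(n_groups)
            for b in range(a + 1, n_groups)
        ]
        if not dists or min(dists) >= cfg.prototype_min_separation:
            break
    else:
        raise ValueError(
            f"could not draw {n_groups} prototypes of length {cfg.n_sites} with "
            f"pairwise Hamming separation >= {cfg.prototype_min_separation}"
        )

    cases = default_case_labels(cfg.n_cases)
    group_of_case = assign_groups(cases, groups)
    group_index = {g: i for i, g in enumerate(groups)}
    flips = rng.random(size=(cfg.n_cases, cfg.n_sites)) < cfg.flip_rate
    matrix = np.empty((cfg.n_cases, cfg.n_sites), dtype=int)
    for ci, case in enumerate(cases):
        proto = protos[group_index[group_of_case[case]]]
        matrix[ci] = np.where(flips[ci], 1 - proto, proto)
    columns = [f"site{j + 1}" for j in range(cfg.n_sites)]
    return (
        pd.DataFrame(matrix, index=cases, columns=columns),
        group_of_case,
        pd.DataFrame(protos, index=list(groups), columns=columns),
    )


# ---------------------------------------------------------------------------
# DEG tables with planted overlap and fold-change correlation


def _shared_core_size(sizes: list[int], target: float) -> int:
    """Integer core size whose induced mean pairwise Jaccard is closest to target.

    Within a group every pair of significant sets shares exactly the core
    (condition-specific genes are disjoint), so J(a, b) = c / (S_a + S_b - c).
    """
    smallest = min(sizes)
    if target == 1.0:
        if len(set(sizes)) > 1:
            raise ValueError("target Jaccard 1 is infeasible with unequal set sizes")
        return smallest
    pairs = [
        (sizes[a], sizes[b])
        for a in range(len(sizes))
        for b in range(a + 1, len(sizes))
    ]

    def mean_j(c: int) -> float:
        return float(np.mean([c / (sa + sb - c) for sa, sb in pairs]))

    best = min(range(smallest + 1), key=lambda c: (abs(mean_j(c) - target), c))
    if abs(mean_j(best) - target) > 0.05:
        raise ValueError(
            f"target Jaccard {target} unreachable with set sizes {sizes} "
            f"(closest achievable {mean_j(best):.3f})"
        )
    return best


def simulate_deg_tables(
    cfg: SimulationConfig,
    n_conditions: int | None = None,
    group_of_condition: dict[str, str] | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Per-condition DEG tables with planted within-group overlap.

    Within each group, significant sets share a common core sized so the
    pairwise Jaccard index matches ``target_jaccard``; the remaining
    condition-specific significant genes are disjoint.  Core genes' log2
    fold changes follow a one-factor bivariate model with pairwise
    correlation ``target_lfc_correlation``.  All other genes of the
    universe get adjusted p-values uniform on (0.05, 1].
    """
    if group_of_condition is None:
        n = cfg.n_conditions if n_conditions is None else n_conditions
        conditions = [f"cond{i + 1}" for i in range(n)]
        group_of_condition = assign_groups(conditions, ("control", "AD"))
    conditions = list(group_of_condition)
    rng = cfg.rng(salt=404)
    universe = np.array([f"G{i + 1:05d}" for i in range(cfg.n_genes)])
    rho = cfg.target_lfc_correlation

    groups: dict[str, list[str]] = {}
    for cond, g in group_of_condition.items():
        groups.setdefault(g, []).append(cond)

    # give each group its own slice of the universe so cross-group overlap
    # does not disturb the planted within-group Jaccard
    sig_genes: dict[str, np.ndarray] = {}
    sig_lfc: dict[str, np.ndarray] = {}
    cursor = 0
    for g, conds in groups.items():
        sizes = [cfg.deg_set_size] * len(conds)
        core = _shared_core_size(sizes, cfg.target_jaccard) if len(conds) > 1 else 0
        need = core + sum(s - core for s in sizes)
        if cursor + need > cfg.n_genes:
            raise ValueError(
                f"gene universe of {cfg.n_genes} too small for the requested sets"
            )
        pool = universe[cursor : cursor + need]
        cursor += need
        core_genes = pool[:core]
        if rho < 0 and len(conds) > 2:
            raise ValueError(
                "negative fold-change correlation requires exactly 2 conditions per group"
            )
        z = rng.normal(0.0, cfg.lfc_sd, size=core)
        offset = core
        for k, cond in enumerate(conds):
            own = pool[offset : offset + sizes[k] - core]
            offset += sizes[k] - core
            if rho >= 0:
                eps = rng.normal(0.0, cfg.lfc_sd, size=core)
                core_lfc = math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps
            else:  # 2 conditions: exact bivariate correlation via Cholesky
                if k == 0:
                    core_lfc = z
                else:
                    eps = rng.normal(0.0, cfg.lfc_sd, size=core)
                    core_lfc = rho * z + math.sqrt(1.0 - rho**2) * eps
            own_lfc = rng.normal(0.0, cfg.lfc_sd, size=len(own))
            sig_genes[cond] = np.concatenate([core_genes, own])
            sig_lfc[cond] = np.concatenate([core_lfc, own_lfc])

    tables: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        genes = sig_genes[cond]
        lfc = sig_lfc[cond]
        sig_padj = rng.uniform(1e-12, cfg.alpha * (1 - 1e-9), size=len(genes))
        table = pd.DataFrame(
            {
                "gene_id": genes,
                "log2fc": lfc,
                "pvalue": sig_padj * rng.uniform(0.1, 1.0, size=len(genes)),
                "padj": sig_padj,
            }
        )
        others = universe[~np.isin(universe, genes)]
        ns_padj = cfg.alpha + rng.random(size=len(others)) * (1 - cfg.alpha)
        rest = pd.DataFrame(
            {
                "gene_id": others,
                "log2fc": rng.normal(0.0, 0.2, size=len(others)),
                "pvalue": ns_padj * rng.uniform(0.1, 1.0, size=len(others)),
                "padj": ns_padj,
            }
        )
        tables[cond] = (
            pd.concat([table, rest], ignore_index=True)
            .sort_values("gene_id", kind="mergesort")
            .reset_index(drop=True)
        )
    return tables, group_of_condition


# ---------------------------------------------------------------------------
# Expression matrices with planted co-expression modules


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, tuple[str, int]], pd.DataFrame]:
    """Genes x samples expression with planted single-factor modules.

    Module genes load on a per-condition latent factor with loading equal to
    the configured latent correlation (so two module genes correlate at its
    square); technical replicates of a condition share the factor up to a
    small replicate noise.  Leftover genes are independent noise.

    Returns (matrix, gene -> module, sample -> (condition, replicate),
    per-condition latent factors as modules x conditions).
    """
    rng = cfg.rng(salt=505)
    total_module_genes = sum(size for size, _ in cfg.module_spec)
    if total_module_genes > cfg.n_genes:
        raise ValueError("module sizes exceed n_genes")
    conditions = [f"cond{i + 1}" for i in range(cfg.n_conditions)]
    samples = [
        f"{cond}_rep{r + 1}" for cond in conditions for r in range(cfg.n_replicates)
    ]
    replicate_map = {
        f"{cond}_rep{r + 1}": (cond, r + 1)
        for cond in conditions
        for r in range(cfg.n_replicates)
    }
    n_samples = len(samples)

    matrix = np.empty((cfg.n_genes, n_samples))
    gene_module: dict[str, str] = {}
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]

    # planted factors are orthogonalized across conditions: with few
    # conditions, i.i.d. draws can correlate strongly by chance, which would
    # contradict the planted claim that the modules are distinct
    n_modules = len(cfg.module_spec)
    raw = rng.normal(size=(cfg.n_conditions, max(n_modules, 1)))
    if n_modules <= cfg.n_conditions - 1:
        # QR against the constant vector first: the remaining columns are
        # mean-zero and mutually orthogonal, i.e. exactly uncorrelated
        ones = np.ones((cfg.n_conditions, 1))
        q, _ = np.linalg.qr(np.hstack([ones, raw]))
        factors = q[:, 1 : n_modules + 1].T * math.sqrt(cfg.n_conditions)
    else:
        log.warning(
            "%d modules with %d conditions; latent factors cannot be made "
            "uncorrelated", n_modules, cfg.n_conditions,
        )
        factors = raw.T[:n_modules]
    latents = np.empty((n_modules, cfg.n_conditions))
    row = 0
    for mi, (size, corr) in enumerate(cfg.module_spec):
        factor_cond = factors[mi]
        latents[mi] = factor_cond
        factor = np.repeat(factor_cond, cfg.n_replicates)
        factor = factor + rng.normal(0.0, cfg.replicate_noise_sd, size=n_samples)
        noise = rng.normal(size=(size, n_samples))
        matrix[row : row + size] = corr * factor + math.sqrt(1 - corr**2) * noise
        for g in genes[row : row + size]:
            gene_module[g] = f"M{mi + 1}"
        row += size
    if row < cfg.n_genes:
        matrix[row:] = rng.normal(size=(cfg.n_genes - row, n_samples))
        for g in genes[row:]:
            gene_module[g] = "background"

    expr = pd.DataFrame(matrix, index=genes, columns=samples)
    latent_df = pd.DataFrame(
        latents,
        index=[f"M{mi + 1}" for mi in range(len(cfg.module_spec))],
        columns=conditions,
    )
    return expr, gene_module, replicate_map, latent_df


# ---------------------------------------------------------------------------
# Standard-curve calibration points


def simulate_standard_curve(
    m: float, c: float, noise_sd: float, n_points: int, seed: int
) -> pd.DataFrame:
    """Calibration points y = m*x + c + Normal(0, noise_sd) at distinct x."""
    if n_points < 2:
        raise ValueError(f"need at least 2 points, got {n_points}")
    rng = np.random.default_rng(seed)
    x = np.arange(1, n_points + 1, dtype=float)
    y = m * x + c + (rng.normal(0.0, noise_sd, size=n_points) if noise_sd > 0 else 0.0)
    return pd.DataFrame({"amount": x, "intensity": y})
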