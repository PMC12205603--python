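"""Phosphosite-level tau quantification from peptide precursor abundances.

For each case and canonical phosphosite, precursor ion abundances of all
phosphopeptides covering the site are combined and compared with the
exact-match unmodified peptides:

    adjusted ratio = modified / (unmodified + pseudo-count)

where the pseudo-count is one tenth of the smallest non-zero unmodified
peptide abundance of that case, guaranteeing a finite ratio when a
phosphopeptide has no unmodified counterpart.  Per case, the detected
ratios are min-max normalized to [0, 1] for heatmap display, and any
detected site maps to 1 in the binary presence/absence view used for case
clustering.  A linear standard curve (band intensity against known tau
amount) supports absolute quantitation of tau in sarkosyl-insoluble
fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sites import (
    IsoformSet,
    SiteKey,
    build_coordinate_map,
    locate_peptide,
    site_to_canonical,
)

log = logging.getLogger(__name__)


@dataclass
class SiteAbundance:
    """Combined modified/unmodified precursor abundance for one (case, site)."""

    case: str
    site: SiteKey
    modified_abundance: float
    unmodified_abundance: float
    n_peptides: int


@dataclass
class SiteRatioMatrix:
    """Cases x sites matrices: adjusted ratios, normalized view, binary view.

    Missing cells (NaN in ``ratios``/``normalized``, 0 in ``binary``) mean
    the site was not detected in that case.
    """

    ratios: pd.DataFrame
    normalized: pd.DataFrame
    binary: pd.DataFrame
    pseudo_counts: pd.Series


def aggregate_site_abundance(
    psm: pd.DataFrame,
    isoforms: IsoformSet | None = None,
    include_ambiguous: bool = False,
) -> list[SiteAbundance]:
    """Combine precursor abundances per (case, canonical site).

    Each phosphopeptide row contributes its full intensity to every site its
    offsets map to (a doubly phosphorylated peptide feeds both sites); the
    unmodified abundance of a site is the summed intensity of rows with the
    identical peptide sequence and no modification.  Peptides occurring at
    more than one isoform position are ambiguous and excluded by default.
    """
    if isoforms is None:
        isoforms = IsoformSet.reference()
    coord_map = build_coordinate_map(isoforms)

    modified: dict[tuple[str, SiteKey], float] = {}
    peptides_per_site: dict[tuple[str, SiteKey], set[str]] = {}
    unmodified: dict[tuple[str, str], float] = {}

    for row in psm.itertuples(index=False):
        if not row.phospho_offsets:
            key = (row.sample_id, row.peptide)
            unmodified[key] = unmodified.get(key, 0.0) + float(row.precursor_abundance)
            continue
        hits = locate_peptide(row.peptide, isoforms)
        canonical_sites = {
            site_to_canonical(acc, start + off - 1, coord_map, isoforms)
            for acc, start in hits
            for off in row.phospho_offsets
        }
        distinct_positions = len(canonical_sites) > len(row.phospho_offsets)
        if distinct_positions and not include_ambiguous:
            log.info("excluding ambiguous peptide %s (multiple origins)", row.peptide)
            continue
        for site in canonical_sites:
            key = (row.sample_id, site)
            modified[key] = modified.get(key, 0.0) + float(row.precursor_abundance)
            peptides_per_site.setdefault(key, set()).add(row.peptide)

    records = []
    for (case, site), mod in sorted(modified.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        peps = peptides_per_site[(case, site)]
        unmod = sum(unmodified.get((case, pep), 0.0) for pep in peps)
        records.append(
            SiteAbundance(
                case=case,
                site=site,
                modified_abundance=mod,
                unmodified_abundance=unmod,
                n_peptides=len(peps),
            )
        )
    return records


def compute_pseudo_count(
    case_unmodified: np.ndarray | list[float], global_minimum: float | None = None
) -> float:
    """One tenth of the smallest non-zero unmodified abundance of the case.

    When a case has no unmodified evidence at all, fall back to the smallest
    non-zero unmodified abundance across all cases (``global_minimum``).
    """
    values = np.asarray(case_unmodified, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size:
        return float(nonzero.min()) / 10.0
    if global_minimum is not None and global_minimum > 0:
        log.warning("case has no unmodified evidence; using global fallback pseudo-count")
        return float(global_minimum) / 10.0
    raise ValueError("no non-zero unmodified abundance available for pseudo-count")


def adjusted_ratio(modified: float, unmodified: float, pseudo: float) -> float:
    """modified / (unmodified + pseudo-count); the pseudo-count is always added."""
    if pseudo <= 0:
        raise ValueError(f"pseudo-count must be positive, got {pseudo}")
    return modified / (unmodified + pseudo)


def normalize_per_case(ratios: pd.Series) -> pd.Series:
    """Min-max scale one case's detected ratios to [0, 1].

    Undetected sites (NaN) stay missing.  A degenerate range (all detected
    ratios equal, or a single detected site) maps every detected site to 1:
    detection with no spread is top-of-scale presence, while blue/0 is
    reserved for the weakest detected signal when a spread exists.
    """
    detected = ratios.dropna()
    if detected.empty:
        return ratios.copy()
    lo, hi = detected.min(), detected.max()
    if hi == lo:
        out = ratios.copy()
        out[detected.index] = 1.0
        return out
    return (ratios - lo) / (hi - lo)


def binarize(ratios: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence view: detected (non-missing) -> 1, undetected -> 0."""
    return ratios.notna().astype(int)


def quantify(
    psm: pd.DataFrame,
    isoforms: IsoformSet | None = None,
    include_ambiguous: bool = False,
    pseudo_mode: str = "always",
    min_modified_abundance: float = 0.0,
) -> SiteRatioMatrix:
    """Full site quantification: aggregate, pseudo-count, ratio, normalize, binarize.

    ``pseudo_mode="always"`` (default) adds the pseudo-count to every
    denominator as in the printed ratio formula; ``"when_missing"`` adds it
    only where the unmodified counterpart is absent.  Sites whose combined
    modified abundance falls below ``min_modified_abundance`` are treated as
    undetected.
    """
    if pseudo_mode not in ("always", "when_missing"):
        raise ValueError(f"pseudo_mode must be 'always' or 'when_missing', got {pseudo_mode!r}")
    records = aggregate_site_abundance(psm, isoforms, include_ambiguous)
    records = [r for r in records if r.modified_abundance > min_modified_abundance]

    # per-case unmodified peptide abundances (rows combined per peptide, as
    # for the ratio numerator/denominator) drive the pseudo-count; collected
    # from the PSM table directly so peptides without modified evidence count too
    unmod_sums: dict[tuple[str, str], float] = {}
    for row in psm.itertuples(index=False):
        if not row.phospho_offsets:
            key = (row.sample_id, row.peptide)
            unmod_sums[key] = unmod_sums.get(key, 0.0) + float(row.precursor_abundance)
    unmod_by_case: dict[str, list[float]] = {}
    for (case, _pep), total in unmod_sums.items():
        unmod_by_case.setdefault(case, []).append(total)
    all_unmod = np.array(
        [v for vals in unmod_by_case.values() for v in vals], dtype=float
    )
    nonzero = all_unmod[all_unmod > 0]
    global_min = float(nonzero.min()) if nonzero.size else None

    cases = sorted({r.case for r in records} | set(unmod_by_case))
    sites = sorted({r.site for r in records})
    ratios = pd.DataFrame(
        np.nan, index=cases, columns=[str(s) for s in sites], dtype=float
    )
    pseudo_counts = pd.Series(index=cases, dtype=float, name="pseudo_count")
    for case in cases:
        pseudo_counts[case] = compute_pseudo_count(
            unmod_by_case.get(case, []), global_minimum=global_min
        )
    for rec in records:
        if pseudo_mode == "when_missing" and rec.unmodified_abundance > 0:
            ratios.loc[rec.case, str(rec.site)] = (
                rec.modified_abundance / rec.unmodified_abundance
            )
        else:
            ratios.loc[rec.case, str(rec.site)] = adjusted_ratio(
                rec.modified_abundance, rec.unmodified_abundance, pseudo_counts[rec.case]
            )

    normalized = ratios.apply(normalize_per_case, axis=1)
    return SiteRatioMatrix(
        ratios=ratios,
        normalized=normalized,
        binary=binarize(ratios),
        pseudo_counts=pseudo_counts,
    )


# ---------------------------------------------------------------------------
# Standard-curve quantitation


@dataclass
class StandardCurve:
    """Linear calibration y = m*x + c of band intensity against tau amount."""

    m: float
    c: float
    r_squared: float


def fit_standard_curve(x, y) -> StandardCurve:
    """Ordinary least squares fit of intensity against known amount."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need at least 2 (x, y) points")
    if np.unique(x).size < 2:
        raise ValueError("all x values identical; slope undefined")
    fit = stats.linregress(x, y)
    return StandardCurve(m=float(fit.slope), c=float(fit.intercept), r_squared=float(fit.rvalue) ** 2)


def invert_standard_curve(y, curve: StandardCurve):
    """Amount of tau for measured intensity y: x = (y - c) / m (elementwise)."""
    if curve.m == 0:
        raise ValueError("slope is zero; curve cannot be inverted")
    y = np.asarray(y, dtype=float)
    x = (y - curve.c) / curve.m
    return float(x) if x.ndim == 0 else x
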