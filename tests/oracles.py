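"""Independent brute-force reimplementations used to cross-check the package.

Everything here is deliberately naive (dict arithmetic, O(n^3) loops) and
shares no code with the implementation under test.
"""

import numpy as np
from scipy.spatial.distance import pdist, squareform


def naive_linkage(X: np.ndarray, method: str) -> np.ndarray:
    """O(n^3) Lance-Williams agglomeration with lowest-index tie-breaking."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    D = squareform(pdist(X))
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    Z = []
    nxt = n
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = sorted((active[ii], active[jj]))
                d = dist[(a, b)]
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d, a, b = best
        na, nb = sizes[a], sizes[b]
        Z.append([a, b, d, na + nb])
        for c in active:
            if c in (a, b):
                continue
            nc = sizes[c]
            dac = dist[tuple(sorted((a, c)))]
            dbc = dist[tuple(sorted((b, c)))]
            if method == "average":
                nd = (na * dac + nb * dbc) / (na + nb)
            elif method == "ward":
                nd = np.sqrt(
                    ((na + nc) * dac**2 + (nb + nc) * dbc**2 - nc * d**2)
                    / (na + nb + nc)
                )
            else:
                raise ValueError(method)
            dist[tuple(sorted((nxt, c)))] = nd
        sizes[nxt] = na + nb
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return np.array(Z)


def brute_force_site_ratios(table, canonical: str, site_positions: dict):
    """Loop-based aggregate -> pseudo-count -> ratio -> min-max normalize.

    ``site_positions`` maps canonical residue position -> site label.
    Returns (ratios, normalized, pseudo_counts) keyed by (case, label) / case.
    """
    unmod: dict = {}
    for r in table.itertuples(index=False):
        if not r.phospho_offsets:
            key = (r.sample_id, r.peptide)
            unmod[key] = unmod.get(key, 0.0) + r.precursor_abundance
    mod: dict = {}
    peps: dict = {}
    for r in table.itertuples(index=False):
        if not r.phospho_offsets:
            continue
        start = canonical.find(r.peptide) + 1
        for off in r.phospho_offsets:
            label = site_positions[start + off - 1]
            key = (r.sample_id, label)
            mod[key] = mod.get(key, 0.0) + r.precursor_abundance
            peps.setdefault(key, set()).add(r.peptide)
    cases = sorted({c for c, _ in unmod} | {c for c, _ in mod})
    pseudo = {}
    for case in cases:
        vals = [v for (c, _), v in unmod.items() if c == case and v > 0]
        pseudo[case] = min(vals) / 10.0
    ratios = {}
    for (case, label), m in mod.items():
        u = sum(unmod.get((case, p), 0.0) for p in peps[(case, label)])
        ratios[(case, label)] = m / (u + pseudo[case])
    normalized = {}
    for case in cases:
        vals = {l: v for (c, l), v in ratios.items() if c == case}
        if not vals:
            continue
        lo, hi = min(vals.values()), max(vals.values())
        for label, v in vals.items():
            normalized[(case, label)] = 1.0 if hi == lo else (v - lo) / (hi - lo)
    return ratios, normalized, pseudo


def brute_force_tom_dissimilarity(a: np.ndarray) -> np.ndarray:
    n = len(a)
    k = [sum(a[i][u] for u in range(n)) for i in range(n)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i][u] * a[u][j] for u in range(n)) + a[i][j]
            out[i, j] = 1.0 - num / (min(k[i], k[j]) + 1.0 - a[i][j])
    return out
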