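"""Co-expression network construction, module detection, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest

from astrotau.network import (
    ModuleAssignment,
    NetworkParams,
    adjacency,
    coexpression_pipeline,
    detect_modules,
    hub_genes,
    module_eigengene,
    pick_soft_threshold,
    scale_free_fit,
    select_uniform_modules,
    tom_dissimilarity,
)
from astrotau.synthetic import SimulationConfig, simulate_expression


def block_expression(rng, sizes, n_samples=30):
    """Blocks of perfectly correlated genes, independent across blocks."""
    rows = []
    for size in sizes:
        base = rng.normal(size=n_samples)
        rows.extend([base] * size)
    genes = [f"G{i}" for i in range(sum(sizes))]
    return pd.DataFrame(np.array(rows), index=genes)


class TestAdjacency:
    def test_perfectly_correlated_pair_has_unit_weight(self, rng):
        expr = block_expression(rng, [2])
        for beta in (1, 6, 12):
            a = adjacency(expr, NetworkParams(beta=beta, signed=False))
            assert a[0, 1] == pytest.approx(1.0)

    def test_power_transform_value(self):
        # correlation 0.5 at power 6 gives 0.015625
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])  # corr 0.8 -- construct exact 0.5 instead
        # build two series with exact correlation 0.5 via orthogonal parts
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        g2 = 0.5 * u + np.sqrt(1 - 0.25) * v
        expr = pd.DataFrame([u, g2], index=["a", "b"])
        a = adjacency(expr, NetworkParams(beta=6, signed=False))
        assert a[0, 1] == pytest.approx(0.5**6)

    def test_diagonal_zero_and_symmetric(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 15)))
        a = adjacency(expr, NetworkParams(beta=6, signed=False))
        assert np.allclose(np.diag(a), 0.0)
        assert np.allclose(a, a.T)

    def test_mean_connectivity_decreases_with_power(self, rng):
        expr = pd.DataFrame(rng.normal(size=(40, 20)))
        params = pick_soft_threshold(expr, powers=range(1, 13))
        ks = [params.mean_connectivity[b] for b in range(1, 13)]
        assert all(a > b for a, b in zip(ks, ks[1:]))


class TestSoftThreshold:
    def test_matches_brute_force_scan_oracle(self):
        cfg = SimulationConfig(seed=7, n_genes=120, module_spec=[(40, 0.8)] * 3)
        expr, _, _, _ = simulate_expression(cfg)
        params = pick_soft_threshold(expr, powers=range(1, 21), r2_target=0.8)

        # independent recomputation of the selection rule
        corr = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(corr, 0.0)
        chosen = None
        fits = {}
        for beta in range(1, 21):
            k = (corr**beta).sum(axis=1)
            fits[beta] = scale_free_fit(k)
            if chosen is None and fits[beta] >= 0.8:
                chosen = beta
        if chosen is None:
            chosen = max(fits, key=lambda b: (fits[b], -b))
        assert params.beta == chosen

    def test_rank_one_data_warns(self, rng, caplog):
        import logging

        expr = block_expression(rng, [12])
        with caplog.at_level(logging.WARNING, logger="astrotau.network"):
            pick_soft_threshold(expr)
        assert any("perfectly correlated" in r.message for r in caplog.records)

    def test_constant_genes_removed_with_warning(self, rng, caplog):
        import logging

        expr = pd.DataFrame(rng.normal(size=(35, 12)))
        expr.iloc[0] = 5.0
        with caplog.at_level(logging.WARNING, logger="astrotau.network"):
            params = pick_soft_threshold(expr)
        assert any("constant" in r.message for r in caplog.records)
        assert params.beta >= 1


class TestTom:
    def test_fully_connected_pair_zero_dissimilarity(self):
        # identical adjacency rows and a_ij = 1
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        d = tom_dissimilarity(a)
        assert d[0, 1] == pytest.approx(0.0)

    def test_zero_adjacency_gives_unit_dissimilarity(self):
        d = tom_dissimilarity(np.zeros((4, 4)))
        off = d[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            d = tom_dissimilarity(a)
            k = a.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert d[i, j] == 0.0
                        continue
                    num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
                    tom = num / (min(k[i], k[j]) + 1 - a[i, j])
                    assert d[i, j] == pytest.approx(1 - tom, abs=1e-12)

    def test_output_in_unit_interval_and_symmetric(self, rng):
        a = rng.random((8, 8)) * 0.9
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        d = tom_dissimilarity(a)
        assert ((d >= 0) & (d <= 1)).all()
        assert np.allclose(d, d.T)

    @pytest.mark.parametrize(
        "bad",
        [
            np.ones((3, 3)),  # nonzero diagonal
            np.eye(3) - 1,  # negative entries
        ],
    )
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            tom_dissimilarity(bad)

    def test_asymmetric_rejected(self):
        a = np.array([[0.0, 0.5, 0.1], [0.4, 0.0, 0.2], [0.1, 0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom_dissimilarity(a)


class TestDetectModules:
    def test_two_perfect_blocks_found_exactly(self, rng):
        expr = block_expression(rng, [15, 15])
        a = adjacency(expr, NetworkParams(beta=6, signed=False))
        d = tom_dissimilarity(a)
        asg = detect_modules(d, list(expr.index), min_module_size=5)
        assert len(asg.modules()) == 2
        first = {g for g, m in asg.labels.items() if m == asg.labels["G0"]}
        assert first == {f"G{i}" for i in range(15)}

    def test_min_module_size_above_n_leaves_all_unassigned(self, rng):
        expr = block_expression(rng, [4, 4])
        d = tom_dissimilarity(adjacency(expr, NetworkParams(6, False)))
        asg = detect_modules(d, list(expr.index), min_module_size=50)
        assert all(m == "unassigned" for m in asg.labels.values())

    def test_gene_order_permutation_invariance(self, rng):
        cfg = SimulationConfig(seed=12, n_genes=90, module_spec=[(30, 0.8)] * 3)
        expr, _, _, _ = simulate_expression(cfg)
        d = tom_dissimilarity(adjacency(expr, NetworkParams(6, False)))
        asg = detect_modules(d, list(expr.index))
        perm = rng.permutation(len(expr))
        expr_p = expr.iloc[perm]
        d_p = tom_dissimilarity(adjacency(expr_p, NetworkParams(6, False)))
        asg_p = detect_modules(d_p, list(expr_p.index))
        # same partition as sets of genes
        def groups(a):
            out = {}
            for g, m in a.labels.items():
                if m != "unassigned":
                    out.setdefault(m, set()).add(g)
            return set(map(frozenset, out.values()))

        assert groups(asg) == groups(asg_p)


class TestEigengene:
    def test_identical_genes_give_their_shared_profile(self, rng):
        expr = block_expression(rng, [6])
        eig = module_eigengene(expr, list(expr.index))
        profile = expr.iloc[0].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        r = np.corrcoef(eig.to_numpy(), z)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # sign convention: aligned with the module mean

    def test_unit_norm(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 12)), index=list("abcde"))
        eig = module_eigengene(expr, list("abcde"))
        assert np.linalg.norm(eig.to_numpy()) == pytest.approx(1.0)

    def test_rank_one_planted_module_tracks_latent_factor(self):
        cfg = SimulationConfig(
            seed=4, n_genes=50, module_spec=[(50, 0.95)], replicate_noise_sd=0.0
        )
        expr, _, _, latents = simulate_expression(cfg)
        eig = module_eigengene(expr, list(expr.index))
        lat = np.repeat(latents.loc["M1"].to_numpy(), cfg.n_replicates)
        assert abs(np.corrcoef(eig.to_numpy(), lat)[0, 1]) >= 0.99

    def test_sign_convention_holds_on_random_modules(self, rng):
        for _ in range(20):
            expr = pd.DataFrame(rng.normal(size=(6, 10)))
            expr.index = [f"g{i}" for i in range(6)]
            eig = module_eigengene(expr, list(expr.index))
            z = (expr - expr.mean(axis=1).values[:, None]) / expr.std(
                axis=1, ddof=0
            ).values[:, None]
            assert np.dot(eig.to_numpy(), z.mean(axis=0).to_numpy()) >= -1e-12

    def test_too_small_module_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 8)), index=list("abc"))
        with pytest.raises(ValueError, match="at least 2"):
            module_eigengene(expr, ["a"])


class TestUniformitySelection:
    def _assignment(self, eig_rows, samples):
        asg = ModuleAssignment(labels={})
        asg.eigengenes = pd.DataFrame.from_dict(
            eig_rows, orient="index", columns=samples
        ).astype(float)
        return asg

    def test_identical_replicates_score_zero_and_select(self):
        samples = ["c1_r1", "c1_r2", "c1_r3", "c2_r1", "c2_r2", "c2_r3"]
        rep_map = {s: (s.split("_")[0], int(s[-1])) for s in samples}
        asg = self._assignment({"M1": [1, 1, 1, 2, 2, 2]}, samples)
        select_uniform_modules(asg, rep_map, sd_threshold=0.0)
        assert asg.uniformity["M1"] == 0.0
        assert asg.selected == {"M1"}

    def test_known_scores_rank_modules(self):
        samples = ["c1_r1", "c1_r2", "c1_r3", "c2_r1", "c2_r2", "c2_r3"]
        rep_map = {s: (s.split("_")[0], int(s[-1])) for s in samples}
        asg = self._assignment(
            {"M1": [1, 1, 1, 2, 2, 2], "M2": [0, 1, 2, 0, 1, 2]}, samples
        )
        select_uniform_modules(asg, rep_map, sd_threshold=0.5)
        assert asg.uniformity["M1"] == 0.0
        assert asg.uniformity["M2"] == pytest.approx(np.std([0, 1, 2]), abs=1e-12)
        assert asg.selected == {"M1"}

    def test_replicate_relabeling_within_condition_is_irrelevant(self):
        samples = ["c1_r1", "c1_r2", "c2_r1", "c2_r2"]
        asg = self._assignment({"M1": [0.1, 0.4, 0.2, 0.2]}, samples)
        rep_map_a = {"c1_r1": ("c1", 1), "c1_r2": ("c1", 2), "c2_r1": ("c2", 1), "c2_r2": ("c2", 2)}
        rep_map_b = {"c1_r1": ("c1", 2), "c1_r2": ("c1", 1), "c2_r1": ("c2", 2), "c2_r2": ("c2", 1)}
        a = select_uniform_modules(self._assignment({"M1": [0.1, 0.4, 0.2, 0.2]}, samples), rep_map_a)
        b = select_uniform_modules(self._assignment({"M1": [0.1, 0.4, 0.2, 0.2]}, samples), rep_map_b)
        assert a.uniformity == b.uniformity

    def test_single_replicate_condition_rejected(self):
        samples = ["c1_r1", "c2_r1", "c2_r2"]
        asg = self._assignment({"M1": [1, 2, 3]}, samples)
        rep_map = {"c1_r1": ("c1", 1), "c2_r1": ("c2", 1), "c2_r2": ("c2", 2)}
        with pytest.raises(ValueError, match="c1"):
            select_uniform_modules(asg, rep_map)


class TestHubGenes:
    def test_rank_one_module_hubs_are_top_connectivity_decile(self, rng):
        cfg = SimulationConfig(seed=5, n_genes=50, module_spec=[(50, 0.95)])
        expr, _, _, _ = simulate_expression(cfg)
        adj = adjacency(expr, NetworkParams(6, False))
        genes = list(expr.index)
        asg = ModuleAssignment(labels={g: "M1" for g in genes})
        asg.eigengenes = pd.DataFrame({"M1": module_eigengene(expr, genes)}).T
        hubs = hub_genes(expr, asg, adj, genes, kme_threshold=0.8)
        connectivity = adj.sum(axis=1)
        cutoff = np.quantile(connectivity, 0.9)
        expected = {g for g, k in zip(genes, connectivity) if k >= cutoff}
        assert set(hubs["M1"]) == expected

    def test_unreachable_kme_threshold_gives_empty_list(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 10)), index=[f"g{i}" for i in range(12)])
        genes = list(expr.index)
        asg = ModuleAssignment(labels={g: "M1" for g in genes})
        asg.eigengenes = pd.DataFrame({"M1": module_eigengene(expr, genes)}).T
        adj = adjacency(expr, NetworkParams(6, False))
        hubs = hub_genes(expr, asg, adj, genes, kme_threshold=1.0)
        assert hubs["M1"] == []

    def test_invariant_to_sample_order(self, rng):
        cfg = SimulationConfig(seed=6, n_genes=40, module_spec=[(40, 0.9)])
        expr, _, _, _ = simulate_expression(cfg)
        genes = list(expr.index)

        def run(e):
            asg = ModuleAssignment(labels={g: "M1" for g in genes})
            asg.eigengenes = pd.DataFrame({"M1": module_eigengene(e, genes)}).T
            return hub_genes(e, asg, adjacency(e, NetworkParams(6, False)), genes)

        perm = rng.permutation(expr.shape[1])
        assert run(expr) == run(expr.iloc[:, perm])


class TestPipeline:
    def test_planted_modules_recovered_with_selection_and_hubs(self):
        cfg = SimulationConfig(seed=21, n_genes=150, module_spec=[(50, 0.8)] * 3)
        expr, gene_module, rep_map, latents = simulate_expression(cfg)
        asg, params = coexpression_pipeline(expr, rep_map)
        assert len(asg.modules()) == 3
        # every planted module maps to exactly one detected module
        for planted in ("M1", "M2", "M3"):
            genes = [g for g, m in gene_module.items() if m == planted]
            detected = {asg.labels[g] for g in genes}
            assert len(detected) == 1
        assert set(asg.uniformity) == set(asg.modules())
        assert all(len(v) >= 1 for v in asg.hubs.values())

    def test_zero_noise_modules_score_zero_and_are_selected(self):
        cfg = SimulationConfig(
            seed=22, n_genes=60, module_spec=[(30, 1.0), (30, 1.0)],
            replicate_noise_sd=0.0,
        )
        expr, _, rep_map, _ = simulate_expression(cfg)
        asg, _ = coexpression_pipeline(expr, rep_map, sd_threshold=1e-9)
        assert len(asg.modules()) == 2
        for m in asg.modules():
            assert asg.uniformity[m] == pytest.approx(0.0, abs=1e-12)
            assert m in asg.selected
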