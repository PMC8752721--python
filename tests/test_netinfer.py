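"""Network inference: TOM, soft power, random-forest weights, topology, hubs."""

import numpy as np
import pandas as pd
import pytest

from keyreg import (
    ExpressionData,
    WeightMatrix,
    coen_weights,
    compute_tom,
    extract_topology,
    filter_poor_models,
    grn_importances,
    hub_metrics,
    infer_network,
    pick_soft_power,
)
from keyreg.netinfer import RegulatorNetwork, _tom_from_adjacency


def tom_bruteforce(adj):
    """O(n^3) triple-loop oracle for the topological overlap measure."""
    a = np.array(adj, dtype=float)
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def _expr(matrix, seed_names="G"):
    samples = [f"S{i}" for i in range(matrix.shape[1])]
    return ExpressionData(
        values=pd.DataFrame(matrix, index=[f"{seed_names}{i}" for i in range(matrix.shape[0])],
                            columns=samples),
        annotations=pd.DataFrame({"group": ["A"] * len(samples)}, index=samples),
    )


class TestTom:
    def test_two_gene_perfect_adjacency(self):
        adj = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        tom = compute_tom(adj)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_three_gene_half_adjacency(self):
        adj = pd.DataFrame(np.full((3, 3), 0.5), index=list("abc"), columns=list("abc"))
        tom = compute_tom(adj)
        # (l + a) / (min k + 1 - a) = (0.25 + 0.5) / (1 + 1 - 0.5)
        assert tom.loc["a", "b"] == pytest.approx(0.5)

    def test_zero_adjacency(self):
        adj = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        tom = compute_tom(adj)
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(10)],
                           columns=[f"g{i}" for i in range(10)])
        tom = compute_tom(adj).to_numpy()
        assert np.abs(tom - tom_bruteforce(a)).max() < 1e-12

    def test_range_symmetry_and_row_restriction(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, size=(12, 12))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        full = _tom_from_adjacency(a)
        assert (full >= -1e-12).all() and (full <= 1 + 1e-12).all()
        assert np.allclose(full, full.T)
        rows = np.array([2, 5, 9])
        part = _tom_from_adjacency(a, rows=rows)
        assert np.allclose(part, full[rows])

    def test_rejects_beta_below_one(self, two_group_expr):
        with pytest.raises(ValueError):
            compute_tom(two_group_expr, beta=0.5)


class TestSoftPower:
    def test_correlated_blocks_reach_target_or_warn(self):
        """Hub-structured data: the chosen power maximizes/attains the fit."""
        rng = np.random.default_rng(0)
        n_samples, n_hubs, per_hub = 100, 5, 10
        blocks = []
        for _ in range(n_hubs):
            hub = rng.normal(size=n_samples)
            blocks.append(hub)
            for _ in range(per_hub):
                blocks.append(hub + rng.normal(0, 0.6, size=n_samples))
        expr = _expr(np.array(blocks))
        beta, table = pick_soft_power(expr, powers=range(1, 13), r2_target=0.85)
        assert beta in range(1, 13)
        chosen_r2 = table.loc[table["power"] == beta, "r2"].iloc[0]
        assert chosen_r2 == table["r2"].max() or chosen_r2 >= 0.85

    def test_independent_noise_warns_and_returns_argmax(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(size=(40, 30)))
        with pytest.warns(UserWarning, match="no power reached"):
            beta, table = pick_soft_power(expr, powers=range(1, 6), r2_target=0.999)
        assert beta == int(table.loc[table["r2"].idxmax(), "power"])

    def test_constant_genes_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 20))
        x[3] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            pick_soft_power(_expr(x), powers=[1, 2])


class TestGrn:
    def _signal_expr(self, seed, n=60):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        target = a.copy()  # exact copy of regulator A
        return _expr(np.vstack([a, b, target]))

    def test_copied_regulator_dominates_importance(self):
        wins = 0
        for seed in range(20):
            expr = self._signal_expr(seed)
            wm, _ = grn_importances(expr, ["G0", "G1"], n_trees=100, seed=seed)
            w_a, w_b = wm.weights.at["G0", "G2"], wm.weights.at["G1", "G2"]
            if w_a > w_b and w_a / (w_a + w_b) > 0.9:
                wins += 1
        assert wins == 20

    def test_noise_target_has_nonpositive_oob(self):
        bad = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(4, 40))  # all genes independent noise
            _, quality = grn_importances(_expr(x), ["G0", "G1", "G2"],
                                         n_trees=100, seed=seed)
            if quality["G3"] <= 0:
                bad += 1
        assert bad >= 22  # >= ~90 % of seeds

    def test_parallel_determinism(self):
        expr = self._signal_expr(0, n=30)
        wm1, q1 = grn_importances(expr, ["G0", "G1"], n_trees=50, seed=3, n_jobs=1)
        wm2, q2 = grn_importances(expr, ["G0", "G1"], n_trees=50, seed=3, n_jobs=4)
        pd.testing.assert_frame_equal(wm1.weights, wm2.weights)
        pd.testing.assert_series_equal(q1, q2)

    def test_disjoint_regulators_rejected(self):
        expr = self._signal_expr(0, n=20)
        with pytest.raises(ValueError):
            grn_importances(expr, ["X1", "X2"], n_trees=10, seed=0)


class TestFilterPoorModels:
    def _wm(self):
        w = pd.DataFrame(np.arange(6, dtype=float).reshape(2, 3),
                         index=["r1", "r2"], columns=["t1", "t2", "t3"])
        return WeightMatrix(weights=w)

    def test_all_good_is_identity(self):
        wm = self._wm()
        quality = pd.Series([0.5, 0.2, 0.9], index=["t1", "t2", "t3"])
        out = filter_poor_models(wm, quality)
        pd.testing.assert_frame_equal(out.weights, wm.weights)

    def test_poor_columns_masked_and_counted(self):
        wm = self._wm()
        quality = pd.Series([-0.3, 0.2, 0.0], index=["t1", "t2", "t3"])
        out = filter_poor_models(wm, quality, threshold=0.0)
        masked = out.weights.isna().all(axis=0)
        assert masked.sum() == (quality <= 0).sum()
        assert set(masked[masked].index) == {"t1", "t3"}


class TestExtractTopology:
    def _wm(self, weights):
        w = pd.DataFrame(weights)
        w.index = [f"r{i}" for i in range(w.shape[0])]
        w.columns = [f"t{j}" for j in range(w.shape[1])]
        return WeightMatrix(weights=w)

    def test_ceil_rule_keeps_single_max_edge(self):
        rng = np.random.default_rng(0)
        wm = self._wm(rng.uniform(0.1, 1, size=(4, 5)))  # 20 candidates
        net = extract_topology(wm, edge_fraction=0.05)
        assert net.n_edges == 1
        assert net.edges["weight"].iloc[0] == pytest.approx(wm.weights.max().max())

    def test_fraction_one_keeps_everything(self):
        wm = self._wm(np.random.default_rng(1).uniform(0.1, 1, size=(3, 4)))
        net = extract_topology(wm, edge_fraction=1.0)
        assert net.n_edges == 12

    @pytest.mark.parametrize("frac", [0.03, 0.17, 0.5, 0.99])
    def test_edge_count_is_exact_ceiling(self, frac):
        rng = np.random.default_rng(5)
        wm = self._wm(rng.uniform(size=(6, 30)))
        net = extract_topology(wm, edge_fraction=frac)
        assert net.n_edges == int(np.ceil(frac * 180))

    def test_tie_broken_lexicographically(self):
        w = pd.DataFrame([[0.5, 0.5], [0.5, 0.9]],
                         index=["r1", "r2"], columns=["ta", "tb"])
        net = extract_topology(WeightMatrix(weights=w), edge_fraction=0.5)
        # top edge is the 0.9; the second slot is a 3-way tie at 0.5 ->
        # lexicographically smallest (regulator, target) wins
        kept = set(zip(net.edges["regulator"], net.edges["target"]))
        assert kept == {("r2", "tb"), ("r1", "ta")}

    def test_invalid_fraction_rejected(self):
        wm = self._wm(np.ones((2, 2)))
        for frac in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                extract_topology(wm, edge_fraction=frac)


class TestHubMetrics:
    def _net(self, edges, regulators):
        df = pd.DataFrame(edges, columns=["regulator", "target", "weight"])
        return RegulatorNetwork(edges=df, regulators=regulators)

    def test_star_out_degree(self):
        net = self._net([("c", f"l{i}", 1.0) for i in range(5)], ["c"])
        m = hub_metrics(net)
        assert m.loc["c", "out_degree"] == 5
        assert (m.loc[[f"l{i}" for i in range(5)], "out_degree"] == 0).all()

    def test_chain_out_closeness(self):
        net = self._net([("a", "b", 1.0), ("b", "c", 1.0)], ["a", "b"])
        m = hub_metrics(net)
        # a reaches {b, c} with distances 1+2=3: (2/3) * (2/2) = 2/3
        assert m.loc["a", "out_closeness"] == pytest.approx(2 / 3)
        # b reaches {c}: (1/1) * (1/2) = 1/2
        assert m.loc["b", "out_closeness"] == pytest.approx(1 / 2)
        assert m.loc["c", "out_closeness"] == 0.0


class TestRecovery:
    """Both backends should recover most planted targets per regulator."""

    @pytest.mark.parametrize("method,seeds", [("coen", range(4)), ("grn", range(3))])
    def test_planted_targets_recovered(self, method, seeds):
        from keyreg import SimulationSpec, simulate_regulators

        fractions = []
        for seed in seeds:
            ds = simulate_regulators(SimulationSpec(
                n_samples=60, n_regulators=8, n_bona_fide=4, targets_min=4,
                targets_max=8, effect_size=3.0, target_noise_sd=0.5, seed=seed))
            n_targets = sum(len(t) for t in ds.target_map.values())
            n_genes = ds.expression.n_genes
            candidates = 8 * (n_genes - 1)
            frac = min(1.0, 1.3 * n_targets / candidates)  # match planted density
            net = infer_network(ds.expression, ds.regulators, method=method,
                                edge_fraction=frac, n_trees=100, seed=seed)
            sets = net.target_sets()
            for reg, truth_targets in ds.target_map.items():
                got = set(sets.get(reg, []))
                fractions.append(len(got & set(truth_targets)) / len(truth_targets))
        assert np.mean(fractions) >= 0.8
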