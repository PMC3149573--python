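import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from qttnet.io import RunConfig
from qttnet.network import (CoexpressionNetwork, adjacency, correlation_matrix,
                            detect_modules, intramodular_connectivity,
                            pick_soft_threshold, tom_dissimilarity)
from qttnet.qtt import residualize
from qttnet.simulate import SimulationDesign, simulate_cohort


def brute_force_tom(a):
    """Triple-loop unsigned TOM dissimilarity."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    K = a.sum(axis=1)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom = (shared + a[i, j]) / (min(K[i], K[j]) + 1.0 - a[i, j])
            d[i, j] = 1.0 - tom
    return d


def random_adjacency(n, rng):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_identical_columns_unit_adjacency(self, toy_pheno):
        v = np.random.default_rng(0).normal(size=16)
        expr = pd.DataFrame({"a": v, "b": v.copy()}, index=toy_pheno.index)
        adj = adjacency(expr, beta=1)
        assert adj.loc["a", "b"] == pytest.approx(1.0)

    def test_power_six_of_half(self):
        rng = np.random.default_rng(1)
        # construct two columns with exact correlation 0.5
        u, v = rng.normal(size=50), rng.normal(size=50)
        u = (u - u.mean()) / u.std()
        v = (v - v.mean()) / v.std()
        v -= u * (u @ v) / (u @ u)
        v /= np.linalg.norm(v) / np.linalg.norm(u)
        x2 = 0.5 * u + np.sqrt(0.75) * v
        expr = pd.DataFrame({"a": u, "b": x2})
        adj = adjacency(expr, beta=6)
        assert adj.loc["a", "b"] == pytest.approx(0.5**6, abs=1e-12)

    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(5, 4)),
                            columns=[f"p{j}" for j in range(4)])
        adj = adjacency(expr, beta=3).to_numpy()
        for i in range(4):
            for j in range(4):
                r = np.corrcoef(expr.iloc[:, i], expr.iloc[:, j])[0, 1]
                assert adj[i, j] == pytest.approx(abs(r) ** 3, abs=1e-12)

    def test_constant_column_zeroed(self):
        expr = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        adj = adjacency(expr, beta=1)
        assert adj.loc["a", "b"] == 0.0
        assert adj.loc["b", "b"] == 1.0

    def test_invalid_beta_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            adjacency(expr, beta=0)


class TestSoftThreshold:
    def test_single_candidate_always_chosen(self, small_cohort):
        pheno, expr, _, _ = small_cohort
        resid = residualize(next(iter(expr.values())), pheno)
        sf = pick_soft_threshold(resid, candidates=[1], r2_cut=0.99)
        assert sf.chosen_beta == 1

    def test_connectivity_monotone_in_beta(self, small_cohort):
        pheno, expr, _, _ = small_cohort
        resid = residualize(next(iter(expr.values())), pheno).iloc[:, :60]
        absr = np.abs(correlation_matrix(resid).to_numpy())
        K_prev = None
        for beta in (1, 2, 4, 8):
            K = (absr**beta).sum(axis=1) - 1.0
            if K_prev is not None:
                assert (K <= K_prev + 1e-12).all()
            K_prev = K

    def test_modular_data_scale_free(self):
        """5 planted modules at rho 0.7: some beta > 1 reaches R2 >= 0.8 and
        the smallest such candidate is the one chosen."""
        for seed in range(1, 6):
            d = SimulationDesign(n_probesets=600, n_tissues=1, n_traits=2,
                                 qtt_traits=(), n_true_qtt=0, n_modules=5,
                                 module_sizes=(60,) * 5,
                                 within_module_correlation=0.7)
            pheno, expr, _ = simulate_cohort(d, seed)
            resid = residualize(next(iter(expr.values())), pheno)
            sf = pick_soft_threshold(resid, range(1, 21), 0.8)
            assert sf.r2(sf.chosen_beta) >= 0.8, (seed, sf.chosen_beta)
            assert sf.chosen_beta > 1
            meeting = sf.table.index[sf.table["r2"] >= 0.8]
            assert sf.chosen_beta == meeting.min()

    def test_degenerate_connectivity_scores_zero(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        sf = pick_soft_threshold(expr, candidates=[1, 2], r2_cut=0.8)
        assert ((sf.table["r2"] >= 0) & (sf.table["r2"] <= 1)).all()


class TestTomDissimilarity:
    def test_two_node_hand_case(self):
        a12 = 0.6
        adj = pd.DataFrame([[1.0, a12], [a12, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        d = tom_dissimilarity(adj)
        expected_tom = a12 / (a12 + 1.0 - a12)   # = a12 with K_i = a12
        assert d.loc["a", "b"] == pytest.approx(1.0 - expected_tom, abs=1e-12)
        assert d.loc["a", "a"] == 0.0

    def test_zero_adjacency_full_distance(self):
        adj = pd.DataFrame(np.eye(4))
        d = tom_dissimilarity(adj).to_numpy()
        off = d[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        a = random_adjacency(6, rng)
        d = tom_dissimilarity(pd.DataFrame(a)).to_numpy()
        np.testing.assert_allclose(d, brute_force_tom(a), atol=1e-12)

    def test_bounds_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            a = random_adjacency(6, rng)
            d = tom_dissimilarity(pd.DataFrame(a)).to_numpy()
            assert (d >= -1e-12).all() and (d <= 1.0 + 1e-12).all()
            np.testing.assert_allclose(d, d.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(d), 0.0)


def planted_block_distance(sizes, within, between, rng):
    n = sum(sizes)
    a = np.full((n, n), between)
    start = 0
    labels = np.zeros(n, dtype=int)
    for m, s in enumerate(sizes, start=1):
        a[start:start + s, start:start + s] = within
        labels[start:start + s] = m
        start += s
    a += rng.uniform(0, 0.005, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    nodes = [f"n{i}" for i in range(n)]
    return pd.DataFrame(a, index=nodes, columns=nodes), labels


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        adj, truth = planted_block_distance([50, 50], 0.8, 0.01, rng)
        d = tom_dissimilarity(adj)
        labels = detect_modules(d, min_module_size=30)
        assert labels.max() == 2
        assert adjusted_rand_score(truth, labels.to_numpy()) > 0.95

    def test_duplicated_block_forms_module(self, toy_pheno):
        rng = np.random.default_rng(6)
        v = rng.normal(size=16)
        cols = {f"dup{k}": v + rng.normal(0, 1e-3, 16) for k in range(40)}
        cols.update({f"ind{k}": rng.normal(size=16) for k in range(40)})
        expr = pd.DataFrame(cols, index=toy_pheno.index)
        adj = adjacency(expr, beta=6)
        labels = detect_modules(tom_dissimilarity(adj), min_module_size=30)
        dup_labels = labels[[c for c in labels.index if c.startswith("dup")]]
        assert dup_labels.nunique() == 1
        assert dup_labels.iloc[0] >= 1

    def test_min_size_larger_than_n_all_unassigned(self):
        rng = np.random.default_rng(7)
        adj, _ = planted_block_distance([10], 0.8, 0.0, rng)
        labels = detect_modules(tom_dissimilarity(adj), min_module_size=50)
        assert (labels == 0).all()

    def test_labels_ordered_by_size(self):
        rng = np.random.default_rng(8)
        adj, _ = planted_block_distance([30, 60, 45], 0.8, 0.01, rng)
        labels = detect_modules(tom_dissimilarity(adj), min_module_size=25)
        sizes = labels[labels > 0].value_counts()
        ordered = sizes.loc[sorted(sizes.index)]
        assert list(ordered) == sorted(ordered, reverse=True)


class TestIntramodularConnectivity:
    def test_singleton_module_zero(self):
        adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        modules = pd.Series([1, 0, 0], index=list("abc"))
        prof = intramodular_connectivity(adj, modules)
        assert prof.loc["a", "K_intra"] == 0.0

    def test_uniform_adjacency_closed_form(self):
        m, a_val = 6, 0.4
        a = np.full((m, m), a_val)
        np.fill_diagonal(a, 1.0)
        nodes = [f"n{i}" for i in range(m)]
        adj = pd.DataFrame(a, index=nodes, columns=nodes)
        modules = pd.Series(1, index=nodes)
        prof = intramodular_connectivity(adj, modules)
        np.testing.assert_allclose(prof["K_intra"], a_val * (m - 1), atol=1e-12)

    def test_conservation_identity(self):
        rng = np.random.default_rng(9)
        a = random_adjacency(12, rng)
        nodes = [f"n{i}" for i in range(12)]
        adj = pd.DataFrame(a, index=nodes, columns=nodes)
        modules = pd.Series([1] * 6 + [2] * 6, index=nodes)
        prof = intramodular_connectivity(adj, modules)
        for m, idx in ((1, slice(0, 6)), (2, slice(6, 12))):
            block = a[idx, idx].copy()
            np.fill_diagonal(block, 0.0)
            upper = np.triu(block).sum()
            total = prof.loc[modules == m, "K_intra"].sum()
            assert total == pytest.approx(2 * upper, abs=1e-10)


class TestCoexpressionModel:
    def test_fit_pipeline(self, small_cohort):
        pheno, expr, truth, _ = small_cohort
        tissue = next(iter(expr))
        members = sorted(truth.modules[tissue])
        resid = residualize(expr[tissue][members], pheno)
        cfg = RunConfig(min_module_size=20)
        res = CoexpressionNetwork(resid, tissue).fit(cfg)
        assert res.beta >= 1
        assert set(res.modules.index) == set(members)
        assert (res.connectivity_profile["K"]
                >= res.connectivity_profile["K_intra"] - 1e-9).all()
        assert (res.connectivity_profile["K"] <= len(members) - 1 + 1e-9).all()
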