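import numpy as np
import pandas as pd
import pytest

from qttnet.io import RunConfig
from qttnet.multitissue import (MultiTissueNetwork, build_multi_tissue_matrix,
                                hub_nodes, inter_tissue_connectivity,
                                module_tissue_enrichment, significant_edges,
                                tissue_pair_connection)
from qttnet.qtt import QTTModel, residualize
from qttnet.simulate import SimulationDesign, simulate_cohort


def make_qtt_set(tissue, members, trait="NEFA"):
    """Minimal QTTSet-like stand-in with a fixed member list."""
    from qttnet.qtt import QTTSet
    table = pd.DataFrame({"p": 0.001, "constant": False,
                          "coef": 1.0, "r_partial": 0.5, "t": 3.0},
                         index=pd.Index(members, name="probeset"))
    return QTTSet(tissue=tissue, trait=trait, alpha=0.01, table=table)


def toy_residuals(tissues, n_probes, n=16, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample")
    return {t: pd.DataFrame(rng.normal(size=(n, n_probes)), index=idx,
                            columns=[f"p{j}" for j in range(n_probes)])
            for t in tissues}


class TestBuildMatrix:
    def test_published_nefa_sizes_give_5148_nodes(self):
        sizes = {"FATB": 458, "GONA": 1113, "AHYP": 1919, "THYG": 655,
                 "HYPO": 1003}
        resid = toy_residuals(sizes, max(sizes.values()), n=4)
        qtt = {t: make_qtt_set(t, [f"p{j}" for j in range(k)])
               for t, k in sizes.items()}
        tagged = build_multi_tissue_matrix(qtt, resid)
        assert tagged.n_nodes == 5148

    def test_single_tissue_ten_nodes(self):
        resid = toy_residuals(["FATB"], 20)
        qtt = {"FATB": make_qtt_set("FATB", [f"p{j}" for j in range(10)])}
        # a second tissue is required downstream but not for building
        tagged = build_multi_tissue_matrix(qtt, resid)
        assert tagged.n_nodes == 10

    def test_shared_probeset_becomes_two_nodes(self):
        resid = toy_residuals(["A", "B"], 5)
        qtt = {"A": make_qtt_set("A", ["p0", "p1"]),
               "B": make_qtt_set("B", ["p0"])}
        tagged = build_multi_tissue_matrix(qtt, resid)
        assert tagged.n_nodes == 3
        assert sorted(tagged.tags.unique()) == ["A", "B"]

    def test_sample_mismatch_rejected(self):
        resid = toy_residuals(["A", "B"], 5)
        resid["B"] = resid["B"].iloc[:10]
        qtt = {t: make_qtt_set(t, ["p0"]) for t in ("A", "B")}
        with pytest.raises(ValueError, match="sample mismatch"):
            build_multi_tissue_matrix(qtt, resid)


class TestInterTissueConnectivity:
    def _tagged_adj(self, a, tags):
        nodes = [f"n{i}" for i in range(a.shape[0])]
        return (pd.DataFrame(a, index=nodes, columns=nodes),
                pd.Series(tags, index=nodes))

    def test_constant_adjacency(self):
        a = np.full((6, 6), 0.35)
        np.fill_diagonal(a, 1.0)
        adj, tags = self._tagged_adj(a, ["A"] * 3 + ["B"] * 3)
        out = inter_tissue_connectivity(adj, tags)
        np.testing.assert_allclose(out, 0.35, atol=1e-12)

    def test_full_connection_upper_bound(self):
        a = np.ones((4, 4))
        adj, tags = self._tagged_adj(a, ["A", "A", "B", "B"])
        out = inter_tissue_connectivity(adj, tags)
        np.testing.assert_allclose(out, 1.0)

    def test_matches_brute_force_on_8_nodes(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tags_list = ["A"] * 3 + ["B"] * 3 + ["C"] * 2
        adj, tags = self._tagged_adj(a, tags_list)
        out = inter_tissue_connectivity(adj, tags)
        for i in range(8):
            ext = [j for j in range(8) if tags_list[j] != tags_list[i]]
            expected = np.mean([a[i, j] for j in ext])
            assert out.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_single_tissue_rejected(self):
        a = np.ones((3, 3))
        adj, tags = self._tagged_adj(a, ["A"] * 3)
        with pytest.raises(ValueError):
            inter_tissue_connectivity(adj, tags)


class TestTissuePairConnection:
    def test_constant_cross_block(self):
        a = np.full((6, 6), 0.3)
        np.fill_diagonal(a, 1.0)
        nodes = [f"n{i}" for i in range(6)]
        adj = pd.DataFrame(a, index=nodes, columns=nodes)
        tags = pd.Series(["A"] * 3 + ["B"] * 3, index=nodes)
        C = tissue_pair_connection(adj, tags)
        assert C.loc["A", "B"] == pytest.approx(0.3)

    def test_symmetry_on_random_input(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (9, 9))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        nodes = [f"n{i}" for i in range(9)]
        adj = pd.DataFrame(a, index=nodes, columns=nodes)
        tags = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=nodes)
        C = tissue_pair_connection(adj, tags)
        for t1 in "ABC":
            for t2 in "ABC":
                if t1 != t2:
                    assert C.loc[t1, t2] == C.loc[t2, t1]

    def test_planted_shared_factor_ranks_first(self):
        """Tissues sharing a latent factor have the strongest connection."""
        rng = np.random.default_rng(3)
        n = 40
        factor = rng.normal(size=n)
        idx = pd.Index([f"s{i}" for i in range(n)])

        def block(loading, cols):
            return pd.DataFrame(
                loading * factor[:, None] + rng.normal(size=(n, cols)),
                index=idx, columns=[f"p{j}" for j in range(cols)])

        values = pd.concat([block(2.0, 10), block(2.0, 10), block(0.0, 10)],
                           axis=1)
        values.columns = [f"{t}::p{j}" for t in "ABC" for j in range(10)]
        tags = pd.Series([t for t in "ABC" for _ in range(10)],
                         index=values.columns)
        from qttnet.network import correlation_matrix
        adj = np.abs(correlation_matrix(values))
        C = tissue_pair_connection(adj, tags)
        assert C.loc["A", "B"] > C.loc["A", "C"]
        assert C.loc["A", "B"] > C.loc["B", "C"]
        # and the shared-factor tissues have the highest median K_inter_std
        kint = inter_tissue_connectivity(adj, tags)
        med = kint.groupby(tags).median()
        assert med["C"] == med.min()


class TestModuleTissueEnrichment:
    def test_pure_tissue_module_extreme(self):
        nodes = [f"n{i}" for i in range(50)]
        modules = pd.Series([1] * 10 + [0] * 40, index=nodes)
        tags = pd.Series(["A"] * 10 + ["B"] * 40, index=nodes)
        df = module_tissue_enrichment(modules, tags)
        row = df[(df["module"] == 1) & (df["tissue"] == "A")].iloc[0]
        other = df[(df["module"] == 1) & (df["tissue"] == "B")].iloc[0]
        assert row["p_raw"] < 1e-6 < other["p_raw"]

    def test_matches_exhaustive_enumeration(self):
        from itertools import combinations
        nodes = [f"n{i}" for i in range(12)]
        modules = pd.Series([1] * 5 + [0] * 7, index=nodes)
        tags = pd.Series(["A"] * 4 + ["B"] * 8, index=nodes)
        df = module_tissue_enrichment(modules, tags)
        obs = 4  # module 1 holds nodes n0..n4, tissue A is n0..n3
        hits = total = 0
        for draw in combinations(range(12), 5):
            total += 1
            if len(set(draw) & set(range(4))) >= obs:
                hits += 1
        row = df[(df["module"] == 1) & (df["tissue"] == "A")].iloc[0]
        assert row["p_raw"] == pytest.approx(hits / total, abs=1e-12)

    def test_balanced_shares_not_significant(self):
        rng = np.random.default_rng(4)
        n = 400
        nodes = [f"n{i}" for i in range(n)]
        modules = pd.Series(rng.integers(1, 4, n), index=nodes)
        tags = pd.Series(rng.choice(list("AB"), n), index=nodes)
        df = module_tissue_enrichment(modules, tags)
        assert (df["p_bh"] > 0.05).all()


class TestHubNodes:
    def _profile(self, n, module=1, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"module": module, "K_intra": rng.uniform(0, 5, n)},
                            index=[f"n{i}" for i in range(n)])

    def test_ceiling_size_convention(self):
        prof = self._profile(1135)
        hubs = hub_nodes(prof, 0.10)
        assert len(hubs[1]) == 114      # ceil(0.10 * 1135)

    def test_fraction_one_all_members(self):
        prof = self._profile(7)
        assert len(hub_nodes(prof, 1.0)[1]) == 7

    def test_top_node_selected(self):
        prof = self._profile(10, seed=1)
        hubs = hub_nodes(prof, 0.1)
        assert hubs[1] == [prof["K_intra"].idxmax()]

    def test_deterministic_tie_break(self):
        prof = pd.DataFrame({"module": 1, "K_intra": 1.0},
                            index=["b", "a", "c", "d"])
        assert hub_nodes(prof, 0.5)[1] == ["a", "b"]


class TestSignificantEdges:
    def test_duplicated_node_retained_positive(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=16)
        values = pd.DataFrame({"a": v, "b": v + rng.normal(0, 1e-9, 16)})
        edges = significant_edges(values, design_rank=0, edge_alpha=1e-4,
                                  edge_fdr=0.05)
        assert len(edges) == 1 and edges.iloc[0]["sign"] == "+"

    def test_null_nodes_produce_no_edges(self):
        rng = np.random.default_rng(6)
        values = pd.DataFrame(rng.normal(size=(16, 100)))
        edges = significant_edges(values, design_rank=5, edge_alpha=1e-4,
                                  edge_fdr=0.05)
        assert len(edges) <= 1

    def test_p_matches_permutation_oracle(self):
        """Analytic two-sided p agrees with a 1e5-shuffle permutation p."""
        rng = np.random.default_rng(7)
        n = 16
        x = rng.normal(size=n)
        y = 0.8 * x + 0.6 * rng.normal(size=n)
        values = pd.DataFrame({"a": x, "b": y})
        edges = significant_edges(values, design_rank=0, edge_alpha=1.0,
                                  edge_fdr=1.0)
        r_obs = edges.iloc[0]["r"]
        p_analytic = edges.iloc[0]["p"]
        perms = np.array([np.corrcoef(x, rng.permutation(y))[0, 1]
                          for _ in range(100_000)])
        p_perm = (np.abs(perms) >= abs(r_obs)).mean()
        assert p_analytic == pytest.approx(p_perm, abs=3e-3)

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)))
        with pytest.raises(ValueError):
            significant_edges(values, design_rank=5)


@pytest.fixture(scope="module", name="fitted")
def fitted_multitissue(small_cohort):
    pheno, expr, truth, design = small_cohort
    cfg = RunConfig(n_qtt_permutations=5, min_module_size=15)
    qtt, resid = {}, {}
    for tissue, mat in expr.items():
        resid[tissue] = residualize(mat, pheno)
        qtt[tissue] = QTTModel(mat, pheno, tissue).fit(
            traits=["NEFA"], compute_fdr=False)["NEFA"]
    model = MultiTissueNetwork(qtt, resid, pheno=pheno)
    return model.fit(cfg), qtt


class TestMultiTissueModel:
    def test_node_count_conserved(self, fitted):
        res, qtt = fitted
        assert res.n_nodes == sum(q.n_observed for q in qtt.values())
        assert len(res.node_table) == res.n_nodes

    def test_connectivity_decomposition(self, fitted):
        """K(i) decomposes exactly into per-module contributions."""
        res, _ = fitted
        a = res.adjacency_df.to_numpy().copy()
        np.fill_diagonal(a, 0.0)
        lab = res.modules.to_numpy()
        K = res.node_table["K"].to_numpy()
        parts = np.zeros_like(K)
        for m in np.unique(lab):
            idx = lab == m
            parts += a[:, idx].sum(axis=1)
        np.testing.assert_allclose(K, parts, atol=1e-9)
        own = res.node_table["K_intra"].to_numpy()
        assert (own <= K + 1e-9).all()

    def test_inter_tissue_in_unit_interval(self, fitted):
        res, _ = fitted
        k = res.node_table["K_inter_std"]
        assert ((k >= 0) & (k <= 1)).all()

    def test_mixed_trait_sets_rejected(self, small_cohort):
        pheno, expr, _, _ = small_cohort
        tissues = list(expr)[:2]
        resid = {t: residualize(expr[t], pheno) for t in tissues}
        qtt = {tissues[0]: make_qtt_set(tissues[0], ["p00001"], trait="NEFA"),
               tissues[1]: make_qtt_set(tissues[1], ["p00001"], trait="ALT")}
        with pytest.raises(ValueError, match="mix traits"):
            MultiTissueNetwork(qtt, resid, pheno=pheno)

    def test_hub_edges_thresholds(self, fitted):
        res, _ = fitted
        if len(res.hub_edges):
            assert (res.hub_edges["p"] < res.config.edge_alpha).all()
            assert (res.hub_edges["q"] < res.config.edge_fdr).all()
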