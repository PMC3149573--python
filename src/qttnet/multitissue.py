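"""Multi-tissue co-expression network over pooled QTT.

For one metabolite, the QTT called in each tissue are pooled into a single
network whose nodes are (tissue, probeset) pairs — a probeset that is a
QTT in two tissues contributes two distinct nodes.  On this network we
compute, besides the usual module/connectivity statistics:

* **standardized inter-tissue connectivity** of node i: the mean adjacency
  from i to all N_ot nodes of other tissues (dimensionless, so tissues
  with very different QTT counts remain comparable);
* **tissue-pair connection strength** C(t1, t2): the mean adjacency over
  all cross-tissue node pairs of tissues t1 and t2;
* **module-tissue enrichment**: a hypergeometric test of each tissue's
  share within each module, BH-corrected;
* **hub nodes**: per module, the ceil(fraction * N_m) nodes of highest
  intramodular connectivity (ties broken by node id);
* **significant signed edges** among hubs: Pearson correlation with a
  two-sided t-test at df = (n - p) - 2, where p design columns were
  removed by sex/breed residualization; edges require nominal p below
  ``edge_alpha`` and BH q below ``edge_fdr`` over the tested hub pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gsea import OrarResult, benjamini_hochberg
from .io import RunConfig
from .network import (correlation_matrix, detect_modules,
                      intramodular_connectivity, pick_soft_threshold,
                      tom_dissimilarity)
from .qtt import QTTSet, design_matrix

__all__ = [
    "TissueTaggedMatrix", "build_multi_tissue_matrix",
    "inter_tissue_connectivity", "tissue_pair_connection",
    "module_tissue_enrichment", "hub_nodes", "significant_edges",
    "MultiTissueNetwork", "MultiTissueResults",
]

TAG_SEP = "::"


@dataclass
class TissueTaggedMatrix:
    """Residual expression of pooled QTT; columns are tissue-tagged nodes."""

    values: pd.DataFrame          # samples x nodes
    tags: pd.Series               # node -> tissue

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def build_multi_tissue_matrix(qtt_sets: dict[str, QTTSet],
                              residuals: dict[str, pd.DataFrame]
                              ) -> TissueTaggedMatrix:
    """Disjoint union of each tissue's QTT columns, tagged by tissue.

    All tissues must cover the same samples (the same animals profiled in
    every tissue).  Node count equals the sum of per-tissue QTT counts.
    """
    tissues = sorted(qtt_sets)
    base_index = None
    blocks, tags = [], {}
    for tissue in tissues:
        resid = residuals[tissue]
        if base_index is None:
            base_index = resid.index
        elif not base_index.equals(resid.index):
            raise ValueError(f"sample mismatch: tissue {tissue!r} does not "
                             "cover the common sample set")
        members = qtt_sets[tissue].members
        block = resid[members].copy()
        block.columns = [f"{tissue}{TAG_SEP}{p}" for p in members]
        for c in block.columns:
            tags[c] = tissue
        blocks.append(block)
    if base_index is None:
        raise ValueError("no tissues provided")
    values = pd.concat(blocks, axis=1)
    return TissueTaggedMatrix(values, pd.Series(tags, name="tissue").loc[values.columns])


def inter_tissue_connectivity(adj: pd.DataFrame, tags: pd.Series) -> pd.Series:
    """Standardized inter-tissue connectivity per node.

    K_inter_std(i) = (1/N_ot) * sum over nodes l of other tissues of a_il,
    i.e. the mean adjacency to external-tissue nodes; values lie in [0,1].
    """
    if tags.nunique() < 2:
        raise ValueError("need >= 2 tissues")
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    lab = tags.loc[adj.index].to_numpy()
    out = np.empty(len(lab))
    for t in np.unique(lab):
        inside = lab == t
        n_ot = int((~inside).sum())
        if n_ot == 0:
            raise ValueError(f"tissue {t!r} has no external nodes")
        out[inside] = a[np.ix_(inside, ~inside)].sum(axis=1) / n_ot
    return pd.Series(out, index=adj.index, name="K_inter_std")


def tissue_pair_connection(adj: pd.DataFrame, tags: pd.Series) -> pd.DataFrame:
    """Mean adjacency over all cross-tissue node pairs, per tissue pair.

    C(t1,t2) = (1/(N_1 N_2)) * sum_{i in t1, j in t2} a_ij; symmetric with
    an empty (NaN) diagonal.
    """
    a = adj.to_numpy(dtype=float)
    lab = tags.loc[adj.index].to_numpy()
    tissues = sorted(np.unique(lab))
    C = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for i, t1 in enumerate(tissues):
        m1 = lab == t1
        for t2 in tissues[i + 1:]:
            m2 = lab == t2
            val = a[np.ix_(m1, m2)].mean()
            C.loc[t1, t2] = C.loc[t2, t1] = val
    return C


def module_tissue_enrichment(modules: pd.Series, tags: pd.Series
                             ) -> pd.DataFrame:
    """Hypergeometric enrichment of each tissue within each module (BH).

    Tests whether module m holds more tissue-t nodes than the tissue's
    overall share predicts; unassigned nodes (label 0) are part of the
    universe but not tested as a module.
    """
    if not modules.index.equals(tags.index):
        raise ValueError("partition and tags must cover the same nodes")
    lab = modules.to_numpy()
    tis = tags.to_numpy()
    N = len(lab)
    rows = []
    for m in sorted(np.unique(lab)):
        if m == 0:
            continue
        in_m = lab == m
        for t in sorted(np.unique(tis)):
            in_t = tis == t
            k = int((in_m & in_t).sum())
            p = float(stats.hypergeom.sf(k - 1, N, int(in_t.sum()), int(in_m.sum())))
            expected = in_m.sum() * in_t.sum() / N
            rows.append({"module": int(m), "tissue": t, "observed": k,
                         "expected": expected,
                         "fold": k / expected if expected else np.nan,
                         "p_raw": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = benjamini_hochberg(df["p_raw"].to_numpy())
    return df


def hub_nodes(profile: pd.DataFrame, fraction: float = 0.10
              ) -> dict[int, list[str]]:
    """Per-module hub sets: the top ceil(fraction * N_m) nodes by K_intra.

    ``profile`` needs columns ``module`` and ``K_intra``; ties are broken
    by node id so hub membership is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    hubs: dict[int, list[str]] = {}
    for m in sorted(profile["module"].unique()):
        if m == 0:
            continue
        sub = profile[profile["module"] == m]
        n_hub = int(np.ceil(fraction * len(sub)))
        order = sorted(sub.index, key=lambda i: (-sub.loc[i, "K_intra"], str(i)))
        hubs[int(m)] = order[:n_hub]
    return hubs


def significant_edges(values: pd.DataFrame, design_rank: int,
                      edge_alpha: float = 1e-4,
                      edge_fdr: float = 0.05) -> pd.DataFrame:
    """Significant signed correlation edges among selected nodes.

    ``values`` holds residual expression (samples x nodes); ``design_rank``
    is the number of design columns removed by residualization, so the
    correlation t-test runs at df = (n - design_rank) - 2.  An edge is kept
    when its two-sided p is below ``edge_alpha`` and its BH q over all
    tested pairs is below ``edge_fdr``.
    """
    n = values.shape[0]
    df = (n - design_rank) - 2
    if df < 1:
        raise ValueError(f"too few samples: effective df = {df}")
    cor = correlation_matrix(values).to_numpy()
    nodes = list(values.columns)
    iu, ju = np.triu_indices(len(nodes), k=1)
    r = np.clip(cor[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = benjamini_hochberg(p)
    keep = (p < edge_alpha) & (q < edge_fdr)
    return pd.DataFrame({
        "node1": [nodes[i] for i in iu[keep]],
        "node2": [nodes[j] for j in ju[keep]],
        "r": r[keep], "p": p[keep], "q": q[keep],
        "sign": np.where(r[keep] >= 0, "+", "-"),
    })


# ---------------------------------------------------------------------------
# model/results front end
# ---------------------------------------------------------------------------

class MultiTissueNetwork:
    """Pooled-QTT network model for one trait across tissues.

    Parameters
    ----------
    qtt_sets : mapping tissue -> QTTSet
        QTT sets for one trait, one per tissue.
    residuals : mapping tissue -> DataFrame
        sex/breed residual expression per tissue, same samples everywhere.
    pheno : DataFrame, optional
        phenotype table used for residualization; supplies the design rank
        for the edge test (falls back to ``design_rank``).
    """

    def __init__(self, qtt_sets: dict[str, QTTSet],
                 residuals: dict[str, pd.DataFrame],
                 pheno: pd.DataFrame | None = None,
                 design_rank: int | None = None):
        traits = {s.trait for s in qtt_sets.values()}
        if len(traits) > 1:
            raise ValueError(f"QTT sets mix traits: {sorted(traits)}")
        self.trait = traits.pop() if traits else ""
        self.qtt_sets = qtt_sets
        self.residuals = residuals
        if design_rank is None:
            if pheno is None:
                raise ValueError("provide pheno or design_rank")
            design_rank = design_matrix(pheno).shape[1]
        self.design_rank = int(design_rank)

    def fit(self, config: RunConfig | None = None,
            beta: int | None = None) -> "MultiTissueResults":
        cfg = config or RunConfig()
        tagged = build_multi_tissue_matrix(self.qtt_sets, self.residuals)
        sf = None
        if beta is None:
            sf = pick_soft_threshold(tagged.values, cfg.beta_candidates,
                                     cfg.scale_free_r2_cut)
            beta = sf.chosen_beta
        cor = correlation_matrix(tagged.values)
        adj = np.abs(cor) ** beta
        dist = tom_dissimilarity(adj)
        modules = detect_modules(dist, cfg.min_module_size)
        conn = intramodular_connectivity(adj, modules)
        conn["K_inter_std"] = inter_tissue_connectivity(adj, tagged.tags)
        conn["tissue"] = tagged.tags
        pair_strength = tissue_pair_connection(adj, tagged.tags)
        enrich = module_tissue_enrichment(modules, tagged.tags)
        hubs = hub_nodes(conn, cfg.hub_fraction)
        hub_list = [h for hs in hubs.values() for h in hs]
        edges = (significant_edges(tagged.values[hub_list], self.design_rank,
                                   cfg.edge_alpha, cfg.edge_fdr)
                 if len(hub_list) >= 2 else pd.DataFrame(
                     columns=["node1", "node2", "r", "p", "q", "sign"]))
        return MultiTissueResults(self, tagged, beta, sf, cor, adj, modules,
                                  conn, pair_strength, enrich, hubs, edges, cfg)


@dataclass
class MultiTissueResults:
    """Fitted multi-tissue network and its inter-tissue statistics."""

    model: MultiTissueNetwork
    tagged: TissueTaggedMatrix
    beta: int
    scale_free: object
    correlations_df: pd.DataFrame
    adjacency_df: pd.DataFrame
    modules: pd.Series
    node_table: pd.DataFrame           # module, K, K_intra, K_inter_std, tissue
    tissue_pair_strength: pd.DataFrame
    module_enrichment: pd.DataFrame
    hubs: dict[int, list[str]]
    hub_edges: pd.DataFrame
    config: RunConfig = field(default_factory=RunConfig)

    # write_network protocol
    @property
    def node_ids(self):
        return list(self.adjacency_df.index)

    @property
    def adjacency(self) -> np.ndarray:
        return self.adjacency_df.to_numpy()

    @property
    def correlations(self) -> np.ndarray:
        return self.correlations_df.to_numpy()

    @property
    def module(self) -> np.ndarray:
        return self.modules.to_numpy()

    @property
    def tissue(self):
        return self.tagged.tags.to_numpy()

    @property
    def n_nodes(self) -> int:
        return self.tagged.n_nodes

    def median_inter_tissue_connectivity(self) -> pd.Series:
        return (self.node_table.groupby("tissue")["K_inter_std"]
                .median().sort_values(ascending=False))

    def summary(self) -> pd.DataFrame:
        sizes = self.modules[self.modules > 0].value_counts().sort_index()
        rows = [{"module": int(m), "size": int(s), "n_hubs": len(self.hubs.get(int(m), []))}
                for m, s in sizes.items()]
        return pd.DataFrame(rows)
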