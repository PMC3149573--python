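"""Weighted gene co-expression networks for a single tissue.

The network is unsigned: Pearson correlations between sex/breed-residualized
expression profiles are transformed into the adjacency a_ij = |r_ij|^beta.
The soft threshold beta is the smallest candidate for which the node
connectivity distribution approximates a scale-free law P(K) ~ K^-gamma
(model fit R^2 of log10 p(K) on log10 K over equal-count bins, requiring a
negative slope).  The adjacency is converted to the topological overlap
dissimilarity

    d_ij = 1 - (sum_u a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 - a_ij),

clustered by average linkage, and modules are detected by an adaptive
(dynamic tree) dendrogram cut: starting from a cut at 99% of the tallest
merge, branches are split while both sub-branches hold at least
``min_module_size`` nodes; everything smaller stays unassigned (label 0).
Modules are relabelled 1..M by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import RunConfig, logger

__all__ = [
    "correlation_matrix", "adjacency", "pick_soft_threshold",
    "tom_dissimilarity", "detect_modules", "intramodular_connectivity",
    "ScaleFreeFit", "CoexpressionNetwork", "CoexpressionResults",
]


def correlation_matrix(expr_residual: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between columns; constant columns get r = 0."""
    values = expr_residual.to_numpy(dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need >= 3 samples for correlations")
    sd = values.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.info("correlation_matrix: %d constant columns flagged, r set 0",
                    int(constant.sum()))
    safe = values.copy()
    safe[:, constant] = 0.0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(safe, rowvar=False)
    r[np.isnan(r)] = 0.0
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=expr_residual.columns,
                        columns=expr_residual.columns)


def adjacency(expr_residual: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Soft-threshold adjacency a_ij = |r_ij|^beta (unit diagonal)."""
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    r = correlation_matrix(expr_residual)
    return np.abs(r) ** beta


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity K_i = sum_{j != i} a_ij."""
    a = adj.to_numpy(dtype=float)
    return pd.Series(a.sum(axis=1) - np.diag(a), index=adj.index, name="K")


def _scale_free_r2(K: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """(R^2, slope) of log10 p(K) vs log10 K over equal-count bins.

    Degenerate distributions or positive slopes score R^2 = 0.
    """
    K = np.asarray(K, dtype=float)
    if np.allclose(K, K[0]):
        return 0.0, 0.0
    # equal-width bins of K: p(K) is the proportion of nodes per bin
    edges = np.linspace(K.min(), K.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, K, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        mask = which == b
        if not mask.any():
            continue
        mean_k = K[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0, 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope > 0:          # scale-free topology requires a decreasing p(K)
        r2 = 0.0
    return float(max(r2, 0.0)), float(slope)


@dataclass
class ScaleFreeFit:
    """Scale-free criterion fit per candidate soft threshold."""

    table: pd.DataFrame        # index beta, columns r2, slope
    chosen_beta: int

    def r2(self, beta: int) -> float:
        return float(self.table.loc[beta, "r2"])


def pick_soft_threshold(expr_residual: pd.DataFrame,
                        candidates=tuple(range(1, 21)),
                        r2_cut: float = 0.8) -> ScaleFreeFit:
    """Choose the smallest beta meeting the scale-free fit cut.

    Falls back to the beta maximizing R^2 when no candidate reaches the
    cut.  Raising beta only shrinks each |r|^beta, so per-node connectivity
    is non-increasing in beta.
    """
    candidates = sorted(set(int(b) for b in candidates))
    if len(candidates) < 1:
        raise ValueError("need at least one candidate beta")
    absr = np.abs(correlation_matrix(expr_residual).to_numpy())
    rows = {}
    for beta in candidates:
        a = absr ** beta
        K = a.sum(axis=1) - 1.0
        rows[beta] = _scale_free_r2(K)
    table = pd.DataFrame(rows, index=["r2", "slope"]).T
    table.index.name = "beta"
    meeting = [b for b in candidates if table.loc[b, "r2"] >= r2_cut]
    chosen = meeting[0] if meeting else int(table["r2"].idxmax())
    return ScaleFreeFit(table, chosen)


def tom_dissimilarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap dissimilarity 1 - TOM (unsigned).

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 - a_ij)
    with d_ii = 0; entries lie in [0, 1] and the matrix is symmetric.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    K = a.sum(axis=1)
    shared = a @ a                      # sum_u a_iu a_uj (u != i, j by zero diag)
    num = shared + a
    den = np.minimum.outer(K, K) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    d = 1.0 - np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=adj.index, columns=adj.columns)


def detect_modules(dist: pd.DataFrame, min_module_size: int = 30,
                   cut_fraction: float = 0.99) -> pd.Series:
    """Adaptive dendrogram cut of a TOM distance matrix into modules.

    Returns a node -> label Series; label 0 marks unassigned nodes, labels
    1..M are ordered by decreasing module size.
    """
    nodes = dist.index
    n = len(nodes)
    if n < min_module_size:
        return pd.Series(0, index=nodes, name="module")
    condensed = squareform(dist.to_numpy(dtype=float), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    root = hierarchy.to_tree(Z)
    h0 = cut_fraction * root.dist if root.dist > 0 else 0.0

    def leaves(node):
        return node.pre_order(lambda x: x.id)

    # maximal subtrees entirely below the starting cut height
    base_clusters = []

    def collect(node):
        if node.is_leaf() or node.dist <= h0:
            base_clusters.append(node)
        else:
            collect(node.left)
            collect(node.right)

    collect(root)

    def split(node):
        """Split while both sub-branches can stand as modules on their own."""
        if (node.is_leaf() or node.left.count < min_module_size
                or node.right.count < min_module_size):
            return [leaves(node)]
        return split(node.left) + split(node.right)

    modules = []
    labels = np.zeros(n, dtype=int)
    for cluster in base_clusters:
        if cluster.count >= min_module_size:
            modules.extend(split(cluster))
    modules.sort(key=len, reverse=True)
    for m, member_ids in enumerate(modules, start=1):
        labels[member_ids] = m
    return pd.Series(labels, index=nodes, name="module")


def intramodular_connectivity(adj: pd.DataFrame,
                              modules: pd.Series) -> pd.DataFrame:
    """Per-node whole-network K and within-module K_intra.

    K_intra(i) sums a_ij over same-module j != i; unassigned nodes (label
    0) get K_intra = 0.
    """
    if not adj.index.equals(modules.index):
        raise ValueError("partition must cover exactly the adjacency nodes")
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    K = a.sum(axis=1)
    lab = modules.to_numpy()
    k_intra = np.zeros(len(lab))
    for m in np.unique(lab):
        if m == 0:
            continue
        idx = np.flatnonzero(lab == m)
        k_intra[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    return pd.DataFrame({"module": lab, "K": K, "K_intra": k_intra},
                        index=adj.index)


# ---------------------------------------------------------------------------
# model/results front end
# ---------------------------------------------------------------------------

class CoexpressionNetwork:
    """Weighted co-expression network model over residualized expression.

    ``expr_residual`` must already be corrected for sex and breed (see
    :func:`qttnet.qtt.residualize`); columns are the network nodes.
    """

    def __init__(self, expr_residual: pd.DataFrame, tissue: str = ""):
        self.expr_residual = expr_residual
        self.tissue = tissue

    def fit(self, config: RunConfig | None = None,
            beta: int | None = None) -> "CoexpressionResults":
        cfg = config or RunConfig()
        sf = None
        if beta is None:
            sf = pick_soft_threshold(self.expr_residual, cfg.beta_candidates,
                                     cfg.scale_free_r2_cut)
            beta = sf.chosen_beta
        cor = correlation_matrix(self.expr_residual)
        adj = np.abs(cor) ** beta
        dist = tom_dissimilarity(adj)
        modules = detect_modules(dist, cfg.min_module_size)
        conn = intramodular_connectivity(adj, modules)
        return CoexpressionResults(self, beta, sf, cor, adj, dist, modules,
                                   conn, cfg)


@dataclass
class CoexpressionResults:
    """Fitted network: adjacency, modules and connectivity profiles."""

    model: CoexpressionNetwork
    beta: int
    scale_free: ScaleFreeFit | None
    correlations_df: pd.DataFrame
    adjacency_df: pd.DataFrame
    dissimilarity: pd.DataFrame
    modules: pd.Series
    connectivity_profile: pd.DataFrame
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
        return [self.model.tissue] * len(self.node_ids)

    def module_sizes(self) -> pd.Series:
        lab = self.modules[self.modules > 0]
        return lab.value_counts().sort_index()

    def summary(self) -> pd.DataFrame:
        sizes = self.module_sizes()
        rows = [{"module": int(m), "size": int(s),
                 "mean_K_intra": float(
                     self.connectivity_profile.loc[self.modules == m, "K_intra"].mean())}
                for m, s in sizes.items()]
        return pd.DataFrame(rows)
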