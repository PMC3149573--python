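"""Gene set enrichment ranked by partial correlation with a metabolite.

Probesets are collapsed to genes by averaging (a gene represented by
several probesets gets the mean of their values per sample), genes are
ranked by their partial correlation with the trait conditional on sex and
breed, and each gene set gets a weighted Kolmogorov-Smirnov enrichment
score: walking down the ranked list, set members increment the running sum
by |metric|^w (normalized over members) and non-members decrement it by
1/(N - N_hit); the ES is the signed maximum deviation from zero.

Significance comes from phenotype-row permutations (the sample rows of the
phenotype table are re-assigned, the list is re-ranked, and every set is
re-scored).  NES = ES / mean(|null ES of the same sign|); the FDR q-value
follows the standard positive/negative-tail procedure: the fraction of
same-sign null NES at least as extreme, divided by the fraction of
same-sign observed NES at least as extreme.

A plain hypergeometric over-representation test with Benjamini-Hochberg
correction is also provided for annotating discrete gene lists (modules).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, child_rng, logger
from .qtt import _complete_samples, _projector, design_matrix

__all__ = [
    "collapse_probesets", "rank_by_partial_correlation", "enrichment_score",
    "GseaResult", "GSEA", "GseaResults", "hypergeometric_enrichment",
    "OrarResult", "benjamini_hochberg",
]


def collapse_probesets(expr: pd.DataFrame, mapping: pd.Series) -> pd.DataFrame:
    """Collapse a probeset matrix to gene level by per-sample averaging.

    Unmapped probesets are dropped (and counted in the log).
    """
    if len(mapping) == 0:
        raise ValueError("empty probeset->gene mapping")
    mapped = expr.columns.intersection(mapping.index)
    n_dropped = expr.shape[1] - len(mapped)
    if n_dropped:
        logger.info("collapse_probesets: %d unmapped probesets dropped", n_dropped)
    if len(mapped) == 0:
        raise ValueError("no probeset in the matrix is covered by the mapping")
    gene_expr = expr[mapped].T.groupby(mapping.loc[mapped]).mean().T
    gene_expr.columns.name = "gene"
    return gene_expr


def _partial_correlations(M: np.ndarray, ry: np.ndarray,
                          E: np.ndarray) -> np.ndarray:
    RE = M @ E
    e_norm = np.linalg.norm(RE, axis=0)
    y_norm = np.linalg.norm(ry)
    r = np.zeros(E.shape[1])
    ok = (e_norm > 0) & (y_norm > 0)
    r[ok] = (RE[:, ok].T @ ry) / (e_norm[ok] * y_norm)
    return np.clip(r, -1.0, 1.0)


def rank_by_partial_correlation(gene_expr: pd.DataFrame, pheno: pd.DataFrame,
                                trait: str) -> pd.Series:
    """Genes sorted by partial correlation with the trait (descending).

    Constant genes get metric 0; ties break lexicographically on gene id
    for reproducibility.
    """
    pheno = _complete_samples(pheno, trait)
    gene_expr = gene_expr.loc[pheno.index]
    X = design_matrix(pheno)
    M = _projector(X.to_numpy())
    ry = M @ pheno[trait].to_numpy(dtype=float)
    r = _partial_correlations(M, ry, gene_expr.to_numpy(dtype=float))
    metric = pd.Series(r, index=gene_expr.columns, name="r_partial")
    order = sorted(metric.index, key=lambda g: (-metric[g], str(g)))
    return metric.loc[order]


def enrichment_score(ranked: pd.Series, members, weight_exponent: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of a gene set against a ranked list.

    Returns ``(ES, running_sum)`` with the running sum evaluated after
    every position of the list.
    """
    genes = ranked.index
    hit = genes.isin(set(members))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked list")
    N = len(genes)
    if n_hit == N:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    hit_weight = np.where(hit, w, 0.0)
    nr = hit_weight.sum()
    if nr == 0:                      # all member metrics exactly 0
        hit_weight = hit.astype(float)
        nr = float(n_hit)
    running = np.cumsum(hit_weight / nr - (~hit) / (N - n_hit))
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_for_sets(order_metric: np.ndarray, hit_masks: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    """ES for many sets on one ranked metric vector (rows of hit_masks)."""
    N = order_metric.shape[0]
    w = np.abs(order_metric) ** weight_exponent
    out = np.empty(hit_masks.shape[0])
    for s in range(hit_masks.shape[0]):
        hit = hit_masks[s]
        n_hit = int(hit.sum())
        hw = np.where(hit, w, 0.0)
        nr = hw.sum()
        if nr == 0:
            hw = hit.astype(float)
            nr = float(n_hit)
        running = np.cumsum(hw / nr - (~hit) / (N - n_hit))
        out[s] = running[np.argmax(np.abs(running))]
    return out


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str]
    size: int


class GSEA:
    """Partial-correlation-ranked gene set enrichment for one trait.

    Parameters
    ----------
    gene_expr : DataFrame
        samples x genes matrix (see :func:`collapse_probesets`).
    pheno : DataFrame
        phenotype table with sex, breed and the trait column.
    trait : str
        metabolite to rank against.
    sets : GeneSetCollection
        candidate gene sets; sets without any gene in the matrix are
        dropped with a log record.
    """

    def __init__(self, gene_expr: pd.DataFrame, pheno: pd.DataFrame,
                 trait: str, sets: GeneSetCollection):
        self.gene_expr = gene_expr
        self.pheno = pheno
        self.trait = trait
        self.sets = sets

    def fit(self, n_perm: int = 1000, weight_exponent: float = 1.0,
            seed: int | np.random.Generator = 0) -> "GseaResults":
        if n_perm < 10:
            raise ValueError("n_perm must be >= 10")
        rng = (seed if isinstance(seed, np.random.Generator)
               else child_rng(seed, "gsea", self.trait))
        pheno = _complete_samples(self.pheno, self.trait)
        expr = self.gene_expr.loc[pheno.index]
        X = design_matrix(pheno)
        M = _projector(X.to_numpy())
        ry = M @ pheno[self.trait].to_numpy(dtype=float)
        E = expr.to_numpy(dtype=float)
        n = E.shape[0]
        genes = np.asarray(expr.columns)

        names, masks = [], []
        for name in self.sets:
            mask = np.isin(genes, list(self.sets.members(name)))
            if mask.any() and not mask.all():
                names.append(name)
                masks.append(mask)
            else:
                logger.info("gsea: set %r has no scorable members, omitted", name)
        if not names:
            raise ValueError("no gene set overlaps the expression matrix")
        masks = np.vstack(masks)

        def ranked_order(r: np.ndarray) -> np.ndarray:
            # descending metric, gene id as deterministic tiebreak
            return np.lexsort((genes.astype(str), -r))

        r_obs = _partial_correlations(M, ry, E)
        order = ranked_order(r_obs)
        es_obs = _es_for_sets(r_obs[order], masks[:, order], weight_exponent)

        es_null = np.empty((n_perm, len(names)))
        for k in range(n_perm):
            r_p = _partial_correlations(M, ry, E[rng.permutation(n)])
            order_p = ranked_order(r_p)
            es_null[k] = _es_for_sets(r_p[order_p], masks[:, order_p],
                                      weight_exponent)

        nes_obs, nes_null, p_nom = self._normalize(es_obs, es_null)
        fdr = self._fdr(nes_obs, nes_null)

        results = []
        ranked = pd.Series(r_obs[order], index=genes[order])
        for i, name in enumerate(names):
            es, running = enrichment_score(ranked, self.sets.members(name),
                                           weight_exponent)
            peak = int(np.argmax(np.abs(running)))
            in_set = ranked.index.isin(set(self.sets.members(name)))
            if es >= 0:
                lead = list(ranked.index[: peak + 1][in_set[: peak + 1]])
            else:
                lead = list(ranked.index[peak:][in_set[peak:]])
            results.append(GseaResult(name, float(es_obs[i]), float(nes_obs[i]),
                                      float(p_nom[i]), float(fdr[i]), lead,
                                      int(masks[i].sum())))
        return GseaResults(self, results, ranked)

    @staticmethod
    def _normalize(es_obs: np.ndarray, es_null: np.ndarray):
        """NES = ES / mean(|same-sign null ES|), per set; nominal p from the
        same-sign null tail."""
        n_perm, n_sets = es_null.shape
        nes_obs = np.zeros(n_sets)
        nes_null = np.zeros_like(es_null)
        p_nom = np.ones(n_sets)
        for i in range(n_sets):
            null = es_null[:, i]
            pos, neg = null[null > 0], null[null < 0]
            mean_pos = pos.mean() if len(pos) else np.nan
            mean_neg = np.abs(neg).mean() if len(neg) else np.nan
            scale = np.where(null >= 0, mean_pos, mean_neg)
            nes_null[:, i] = np.divide(null, scale, out=np.zeros_like(null),
                                       where=~np.isnan(scale) & (scale > 0))
            es = es_obs[i]
            if es >= 0:
                same = pos
                nes_obs[i] = es / mean_pos if len(pos) and mean_pos > 0 else 0.0
                p_nom[i] = ((same >= es).sum() + 1) / (len(same) + 1) if len(same) else 1.0
            else:
                same = neg
                nes_obs[i] = es / mean_neg if len(neg) and mean_neg > 0 else 0.0
                p_nom[i] = ((same <= es).sum() + 1) / (len(same) + 1) if len(neg) else 1.0
        return nes_obs, nes_null, p_nom

    @staticmethod
    def _fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
        """Positive/negative-tail FDR over normalized scores."""
        null = nes_null.ravel()
        null_pos, null_neg = null[null >= 0], null[null < 0]
        obs_pos, obs_neg = nes_obs[nes_obs >= 0], nes_obs[nes_obs < 0]
        q = np.ones_like(nes_obs)
        for i, nes in enumerate(nes_obs):
            if nes >= 0:
                num = (null_pos >= nes).mean() if len(null_pos) else 1.0
                den = (obs_pos >= nes).mean() if len(obs_pos) else 1.0
            else:
                num = (null_neg <= nes).mean() if len(null_neg) else 1.0
                den = (obs_neg <= nes).mean() if len(obs_neg) else 1.0
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        return q


class GseaResults:
    """Per-set enrichment scores, NES, nominal p and FDR q."""

    def __init__(self, model: GSEA, results: list[GseaResult], ranked: pd.Series):
        self.model = model
        self.results = results
        self.ranked = ranked

    def __getitem__(self, name: str) -> GseaResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [{"set": r.name, "size": r.size, "ES": r.es, "NES": r.nes,
              "p_nominal": r.p_nominal, "FDR_q": r.fdr_q} for r in self.results])
        return df.sort_values("NES", ascending=False).reset_index(drop=True)

    def top_pathways(self, n: int = 5) -> pd.DataFrame:
        """Top-n positive and top-n negative NES sets (Figure-2-style)."""
        df = self.summary()
        pos = df[df["NES"] > 0].head(n)
        neg = df[df["NES"] < 0].tail(n)
        return pd.concat([pos, neg]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# over-representation with BH correction
# ---------------------------------------------------------------------------

@dataclass
class OrarResult:
    category: str
    overlap: int
    set_size: int
    fold: float | None
    p_raw: float
    p_bh: float


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (min over j>=i of p_j * m / j)."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float),
                                         method="bh")


def hypergeometric_enrichment(members, universe, sets: GeneSetCollection
                              ) -> list[OrarResult]:
    """Over-representation of ``members`` within ``universe`` per category.

    p_raw is the hypergeometric upper tail of the observed overlap;
    p_bh adjusts across the categories actually tested.
    """
    members = set(members)
    universe = set(universe)
    if not members:
        raise ValueError("empty member list")
    if not members <= universe:
        raise ValueError("members must be a subset of the universe")
    N, n = len(universe), len(members)
    rows = []
    for name in sets:
        cat = set(sets.members(name)) & universe
        if not cat:
            continue
        k = len(cat & members)
        K = len(cat)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K else None
        rows.append((name, k, K, fold, p))
    if not rows:
        return []
    p_bh = benjamini_hochberg([r[4] for r in rows])
    return [OrarResult(name, k, K, fold, p, float(q))
            for (name, k, K, fold, p), q in zip(rows, p_bh)]
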