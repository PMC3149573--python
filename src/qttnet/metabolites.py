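"""Sex and breed effects on plasma metabolites; trait correlations; breed
dendrograms.

The effect model is an ordinary two-factor linear model

    trait ~ intercept + sex + breed

with factor p-values from partial (Type II) F-tests — the F-test for
dropping all of a factor's indicator columns from the full model.  Type II
tests are order-invariant, which matters under the mild sex x breed
imbalance of small cohorts.

Breed dendrograms cluster breeds by 1 - r, where r is the Pearson
correlation between standardized per-breed mean profiles: a perfect
positive correlation gives height 0, no correlation 1, and a perfect
negative correlation 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import trait_names

__all__ = [
    "fit_sex_breed", "trait_correlations", "breed_dendrogram",
    "breed_trait_profiles", "breed_expression_profiles",
    "EffectTestResult", "BreedDendrogram", "SexBreedModel", "SexBreedResults",
]


@dataclass
class EffectTestResult:
    trait: str
    mean: float
    sd: float
    p_sex: float
    p_breed: float
    level_means: dict[str, float]
    level_sds: dict[str, float]


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(np.linalg.matrix_rank(X))


def fit_sex_breed(pheno: pd.DataFrame, trait: str) -> EffectTestResult:
    """Two-factor linear model of one metabolite on sex and breed.

    A zero-variance trait has no testable effects; both p-values are
    reported as 1.0.
    """
    sub = pheno[~pheno[trait].isna()]
    y = sub[trait].to_numpy(dtype=float)
    n = len(y)
    sex = pd.get_dummies(sub["sex"], prefix="sex", drop_first=True).to_numpy(float)
    breed = pd.get_dummies(sub["breed"], prefix="breed", drop_first=True).to_numpy(float)
    icept = np.ones((n, 1))
    X_full = np.hstack([icept, sex, breed])
    rss_full, rank_full = _rss(y, X_full)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError(f"trait {trait!r}: no residual degrees of freedom "
                         f"(n={n}, model rank {rank_full})")

    level_means, level_sds = {}, {}
    for factor in ("sex", "breed"):
        for lev, grp in sub.groupby(factor)[trait]:
            level_means[f"{factor}:{lev}"] = float(grp.mean())
            level_sds[f"{factor}:{lev}"] = float(grp.std(ddof=1)) if len(grp) > 1 else 0.0

    if np.allclose(y, y[0]):
        return EffectTestResult(trait, float(y.mean()), 0.0, 1.0, 1.0,
                                level_means, level_sds)

    pvals = {}
    for name, X_red in (("sex", np.hstack([icept, breed])),
                        ("breed", np.hstack([icept, sex]))):
        rss_red, rank_red = _rss(y, X_red)
        df_num = rank_full - rank_red
        if df_num <= 0 or rss_full <= 0:
            pvals[name] = 1.0
            continue
        F = ((rss_red - rss_full) / df_num) / (rss_full / df_resid)
        pvals[name] = float(stats.f.sf(max(F, 0.0), df_num, df_resid))

    return EffectTestResult(trait, float(y.mean()), float(np.std(y, ddof=1)),
                            pvals["sex"], pvals["breed"], level_means, level_sds)


def trait_correlations(pheno: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise-complete Pearson correlations among the metabolites.

    Returns ``(corr, constant_traits)``: constant traits get correlation 0
    off-diagonal and are listed in the flag list.
    """
    traits = trait_names(pheno)
    data = pheno[traits].astype(float)
    counts = (~data.isna()).astype(int)
    pair_n = counts.T @ counts
    if (pair_n.to_numpy()[~np.eye(len(traits), dtype=bool)] < 3).any():
        raise ValueError("need >= 3 complete pairs for every trait pair")
    corr = data.corr(method="pearson", min_periods=3)
    constant = [t for t in traits if data[t].std(skipna=True) == 0 or data[t].count() < 2]
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr, constant


@dataclass
class BreedDendrogram:
    """Average-linkage tree of breeds on the 1 - r correlation distance."""

    labels: list[str]
    linkage: np.ndarray          # scipy linkage matrix
    distances: pd.DataFrame      # 1 - r between breed profiles

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_h):
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_h - 0.0:.6f}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{parent_h - node.dist:.6f}"

        return recurse(tree, tree.dist).rsplit(":", 1)[0] + ";"


def breed_dendrogram(profiles: dict[str, np.ndarray]) -> BreedDendrogram:
    """Cluster breeds by 1 - Pearson r between their mean profiles.

    Heights live in [0, 2] (0 = identical profiles, 2 = exactly opposite).
    Correlation is affine-invariant, so any per-profile rescaling leaves
    the tree unchanged.  Zero-variance profiles are rejected.
    """
    labels = sorted(profiles)
    if len(labels) < 2:
        raise ValueError("need at least 2 breeds")
    mat = np.vstack([np.asarray(profiles[b], dtype=float) for b in labels])
    if mat.shape[1] < 3:
        raise ValueError("profiles must have length >= 3")
    sds = mat.std(axis=1)
    if (sds == 0).any():
        bad = [labels[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance profile(s): {bad}")
    r = np.corrcoef(mat)
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    dist_df = pd.DataFrame(dist, index=labels, columns=labels)
    return BreedDendrogram(labels, Z, dist_df)


def breed_trait_profiles(pheno: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-breed mean of z-scored metabolite values (trait-space profiles)."""
    traits = trait_names(pheno)
    z = pheno[traits].astype(float)
    z = (z - z.mean()) / z.std(ddof=1)
    return {b: grp[traits].mean().to_numpy()
            for b, grp in z.join(pheno["breed"]).groupby("breed")}


def breed_expression_profiles(expr: pd.DataFrame,
                              pheno: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-breed mean of per-probeset z-scores (expression-space profiles).

    A plain z-score summary of breed expression; probesets with zero
    variance across samples are dropped.
    """
    sd = expr.std(ddof=1)
    keep = expr.loc[:, sd > 0]
    z = (keep - keep.mean()) / keep.std(ddof=1)
    return {b: z.loc[grp.index].mean().to_numpy()
            for b, grp in pheno.groupby("breed")}


# ---------------------------------------------------------------------------
# model/results front end
# ---------------------------------------------------------------------------

class SexBreedModel:
    """Sex/breed effect model over all metabolites of a phenotype table."""

    def __init__(self, pheno: pd.DataFrame):
        self.pheno = pheno

    def fit(self) -> "SexBreedResults":
        results = {t: fit_sex_breed(self.pheno, t) for t in trait_names(self.pheno)}
        return SexBreedResults(self, results)


class SexBreedResults:
    def __init__(self, model: SexBreedModel, results: dict[str, EffectTestResult]):
        self.model = model
        self.results = results

    def __getitem__(self, trait: str) -> EffectTestResult:
        return self.results[trait]

    def summary(self) -> pd.DataFrame:
        """Per-trait mean (SD) and sex/breed p-values."""
        rows = [{"trait": t, "mean": r.mean, "sd": r.sd,
                 "p_sex": r.p_sex, "p_breed": r.p_breed}
                for t, r in self.results.items()]
        return pd.DataFrame(rows).set_index("trait")
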