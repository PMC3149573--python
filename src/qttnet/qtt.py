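"""Quantitative trait transcript (QTT) calling.

For each probeset the model is

    trait ~ intercept + sex + breed + expression

and the probeset is a QTT for the trait when the two-sided t-test on the
expression coefficient gives nominal p < alpha (default 0.01).  Because sex
and breed are adjusted, the t-test is equivalent to the partial correlation
between sex/breed-residualized trait and expression:

    t = r * sqrt(df) / sqrt(1 - r^2),   df = n - p - 1,

where p is the rank of the covariate design (intercept + sex + breed
indicators).  Both routes are implemented; they agree to machine precision
and the regression route is retained as an internal cross-check.

The false discovery rate is estimated by permutation: whole phenotype rows
(trait together with sex and breed) are re-assigned to samples, which
preserves the correlation structure of the transcriptome and the
trait-covariate structure; FDR = mean permuted QTT count / observed count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RunConfig, child_rng, logger, trait_names

__all__ = [
    "design_matrix", "residualize", "association_stats", "call_qtt",
    "permutation_fdr", "QTTSet", "QTTModel", "QTTResults",
]


def design_matrix(pheno: pd.DataFrame) -> pd.DataFrame:
    """Covariate design: intercept + sex + breed treatment indicators.

    Raises ``ValueError`` naming the confounded factor if the design is
    rank deficient.
    """
    X = pd.DataFrame({"intercept": 1.0}, index=pheno.index)
    for factor in ("sex", "breed"):
        dummies = pd.get_dummies(pheno[factor], prefix=factor, drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for factor in ("sex", "breed"):
            cols = ["intercept"] + [c for c in X.columns if not c.startswith(factor)]
            sub = X[[c for c in X.columns if c in cols]]
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                raise ValueError(f"design is rank deficient: factor {factor!r} "
                                 "is confounded with the others")
        raise ValueError("design matrix is rank deficient")
    return X


def _projector(X: np.ndarray) -> np.ndarray:
    """Annihilator I - H for the design X (H the hat matrix)."""
    q, _ = np.linalg.qr(X)
    return np.eye(X.shape[0]) - q @ q.T


def residualize(values, pheno: pd.DataFrame):
    """Residuals of columns of ``values`` after removing intercept+sex+breed.

    ``values`` is a Series or DataFrame indexed by sample.  The operation
    is the orthogonal projection (I - H) and is idempotent; returned
    residual columns are orthogonal to every design column.
    """
    is_series = isinstance(values, pd.Series)
    frame = values.to_frame() if is_series else values
    frame = frame.loc[pheno.index]
    X = design_matrix(pheno)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    M = _projector(X.to_numpy())
    resid = pd.DataFrame(M @ frame.to_numpy(), index=frame.index,
                         columns=frame.columns)
    return resid.iloc[:, 0] if is_series else resid


def _complete_samples(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = pheno[~pheno[trait].isna()]
    if sub["sex"].nunique() < 2 or sub["breed"].nunique() < 2:
        raise ValueError(f"trait {trait!r}: after dropping missing values "
                         "sex/breed no longer have 2+ levels")
    return sub


def association_stats(expr: pd.DataFrame, pheno: pd.DataFrame,
                      trait: str) -> pd.DataFrame:
    """Per-probeset association of expression with a trait, sex/breed adjusted.

    Returns a DataFrame indexed by probeset with columns ``coef`` (the
    expression coefficient of the full regression), ``r_partial``, ``t``,
    ``p`` and boolean ``constant`` (zero residual variance: p set to 1 and
    excluded from QTT membership).
    """
    pheno = _complete_samples(pheno, trait)
    common = expr.index.intersection(pheno.index)
    if len(common) < len(pheno.index):
        raise ValueError("expression and phenotype tables disagree on samples")
    expr = expr.loc[pheno.index]
    X = design_matrix(pheno)
    n, p = X.shape
    df = n - p - 1
    if df < 2:
        raise ValueError(f"residual df = {df} < 2 (n={n}, design rank {p})")

    M = _projector(X.to_numpy())
    ry = M @ pheno[trait].to_numpy(dtype=float)
    RE = M @ expr.to_numpy(dtype=float)

    y_norm = np.linalg.norm(ry)
    e_norm = np.linalg.norm(RE, axis=0)
    tol = 1e-12 * max(1.0, float(np.abs(expr.to_numpy()).max()))
    constant = e_norm <= tol * np.sqrt(n)
    if y_norm == 0.0:
        r = np.zeros(expr.shape[1])
        coef = np.zeros(expr.shape[1])
    else:
        safe = np.where(constant, 1.0, e_norm)
        r = (RE.T @ ry) / (safe * y_norm)
        coef = (RE.T @ ry) / safe**2
    r = np.clip(np.where(constant, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df) / np.sqrt(np.maximum(1.0 - r**2, 1e-300))
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    pval = np.where(constant, 1.0, pval)
    n_const = int(constant.sum())
    if n_const:
        logger.info("association_stats(%s): %d constant probesets skipped",
                    trait, n_const)
    return pd.DataFrame(
        {"coef": np.where(constant, 0.0, coef), "r_partial": r,
         "t": np.where(constant, 0.0, t), "p": pval, "constant": constant},
        index=expr.columns,
    )


@dataclass
class QTTSet:
    """QTT for one (tissue, trait): membership plus permutation FDR."""

    tissue: str
    trait: str
    alpha: float
    table: pd.DataFrame                 # association_stats output, all probesets
    n_permutations: int = 0
    permuted_mean_count: float | None = None

    @property
    def members(self) -> list[str]:
        keep = (self.table["p"] < self.alpha) & ~self.table["constant"]
        return list(self.table.index[keep])

    @property
    def n_observed(self) -> int:
        return len(self.members)

    @property
    def fdr_estimate(self) -> float | None:
        """mean permuted count / observed count; None when undefined."""
        if self.permuted_mean_count is None or self.n_observed == 0:
            return None
        return float(self.permuted_mean_count) / self.n_observed

    def member_table(self) -> pd.DataFrame:
        return self.table.loc[self.members].sort_values("p")


def call_qtt(expr: pd.DataFrame, pheno: pd.DataFrame, trait: str,
             alpha: float = 0.01, tissue: str = "") -> QTTSet:
    """QTT membership at nominal p < alpha for one tissue and trait."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    table = association_stats(expr, pheno, trait)
    return QTTSet(tissue=tissue, trait=trait, alpha=alpha, table=table)


def permutation_fdr(expr: pd.DataFrame, pheno: pd.DataFrame, trait: str,
                    alpha: float, n_perm: int,
                    seed: int | np.random.Generator) -> tuple[float | None, float]:
    """Permutation FDR of the QTT set for one trait.

    Phenotype rows (trait and covariates together) are randomly re-assigned
    to samples; equivalently the expression rows are permuted while the
    phenotype table is fixed, which preserves the transcriptome correlation
    structure exactly.  Returns ``(fdr, mean_permuted_count)``; ``fdr`` is
    None when the observed count is zero (0/0 undefined).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed, "qtt-fdr", trait)
    pheno = _complete_samples(pheno, trait)
    expr = expr.loc[pheno.index]
    X = design_matrix(pheno)
    n, p = X.shape
    df = n - p - 1
    M = _projector(X.to_numpy())
    ry = M @ pheno[trait].to_numpy(dtype=float)
    y_norm = np.linalg.norm(ry)
    E = expr.to_numpy(dtype=float)
    t_cut = stats.t.isf(alpha / 2.0, df)
    r_cut = t_cut / np.sqrt(df + t_cut**2)

    def count(mat: np.ndarray) -> int:
        RE = M @ mat
        e_norm = np.linalg.norm(RE, axis=0)
        ok = e_norm > 0
        r = np.zeros(mat.shape[1])
        if y_norm > 0:
            r[ok] = (RE[:, ok].T @ ry) / (e_norm[ok] * y_norm)
        return int((np.abs(r) > r_cut).sum())

    observed = count(E)
    perm_counts = np.empty(n_perm)
    for k in range(n_perm):
        perm_counts[k] = count(E[rng.permutation(n)])
    mean_perm = float(perm_counts.mean())
    fdr = None if observed == 0 else mean_perm / observed
    return fdr, mean_perm


# ---------------------------------------------------------------------------
# model/results front end
# ---------------------------------------------------------------------------

class QTTModel:
    """Covariate-adjusted trait-transcript association model for one tissue.

    Parameters
    ----------
    expr : DataFrame
        samples x probesets log-intensity matrix.
    pheno : DataFrame
        sample-indexed table with ``sex``, ``breed`` and metabolite columns.
    tissue : str
        label carried into results.
    """

    def __init__(self, expr: pd.DataFrame, pheno: pd.DataFrame, tissue: str = ""):
        self.expr = expr
        self.pheno = pheno
        self.tissue = tissue

    def fit(self, traits: list[str] | None = None,
            config: RunConfig | None = None,
            compute_fdr: bool = True) -> "QTTResults":
        cfg = config or RunConfig()
        traits = traits if traits is not None else trait_names(self.pheno)
        sets: dict[str, QTTSet] = {}
        for trait in traits:
            qs = call_qtt(self.expr, self.pheno, trait, cfg.qtt_alpha, self.tissue)
            if compute_fdr:
                rng = cfg.child_rng("qtt-fdr", self.tissue, trait)
                _, mean_perm = permutation_fdr(
                    self.expr, self.pheno, trait, cfg.qtt_alpha,
                    cfg.n_qtt_permutations, rng)
                qs.n_permutations = cfg.n_qtt_permutations
                qs.permuted_mean_count = mean_perm
            sets[trait] = qs
        return QTTResults(self, sets, cfg)


class QTTResults:
    """Fitted QTT sets for one tissue across traits."""

    def __init__(self, model: QTTModel, sets: dict[str, QTTSet], config: RunConfig):
        self.model = model
        self.sets = sets
        self.config = config

    def __getitem__(self, trait: str) -> QTTSet:
        return self.sets[trait]

    def counts(self) -> pd.Series:
        return pd.Series({t: s.n_observed for t, s in self.sets.items()},
                         name=self.model.tissue or "n_qtt")

    def summary(self) -> pd.DataFrame:
        rows = []
        for trait, s in self.sets.items():
            rows.append({
                "tissue": s.tissue, "trait": trait, "n_qtt": s.n_observed,
                "alpha": s.alpha, "n_permutations": s.n_permutations,
                "permuted_mean": s.permuted_mean_count,
                "fdr": s.fdr_estimate,
            })
        return pd.DataFrame(rows)
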