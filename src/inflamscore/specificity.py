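"""Random-gene-set empirical null for composite-score associations.

Draws many same-size gene sets from the measured gene universe, scores each
with the quartile composite score, fits the same SEP model used for the
observed panel, and locates the observed association p-value within the
resulting null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import MODEL_LADDER, analysis_set, build_design

__all__ = ["NullDistribution", "random_geneset_null", "empirical_p"]


def empirical_p(k: int, n_sets: int, plus_one: bool = False) -> float:
    """Empirical p from the count of null p-values strictly below the
    observed one: k/N, or the add-one form (k+1)/(N+1)."""
    if not 0 <= k <= n_sets:
        raise ValueError("k must lie in [0, n_sets]")
    return (k + 1) / (n_sets + 1) if plus_one else k / n_sets


@dataclass
class NullDistribution:
    """Null association p-values of random gene sets and the observed rank."""

    n_sets: int
    set_size: int
    null_p: np.ndarray
    null_beta: np.ndarray
    observed_p: float
    seed: int | None = None

    @property
    def k(self) -> int:
        """Count of null p-values strictly below the observed p."""
        return int((self.null_p < self.observed_p).sum())

    @property
    def empirical_p(self) -> float:
        return empirical_p(self.k, self.n_sets)

    @property
    def empirical_p_add_one(self) -> float:
        return empirical_p(self.k, self.n_sets, plus_one=True)

    def summary(self) -> dict:
        return {"n_sets": self.n_sets, "set_size": self.set_size,
                "k": self.k, "empirical_p": self.empirical_p,
                "empirical_p_add_one": self.empirical_p_add_one,
                "observed_p": self.observed_p, "seed": self.seed}


def _quartile_indicator(expr: pd.DataFrame, q: float = 0.75) -> np.ndarray:
    vals = expr.to_numpy(float)
    thr = np.quantile(vals, q, axis=1, method="linear")
    return (vals > thr[:, None]).astype(np.float64)


def _vector_ols_pvalues(X: np.ndarray, Y: np.ndarray,
                        col: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Exposure betas and two-sided t-test p-values for many responses."""
    from scipy import stats

    n = X.shape[0]
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    B = H @ Y                                   # p x m
    resid = Y - X @ B
    df = n - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[col, col])
    t = B[col] / se
    return B[col], 2 * stats.t.sf(np.abs(t), df)


def random_geneset_null(expr: pd.DataFrame, meta: pd.DataFrame,
                        sep: str = "sep_early",
                        set_size: int = 845,
                        n_sets: int = 1000,
                        seed: int | None = None,
                        observed_genes: list[str] | None = None,
                        observed_p: float | None = None,
                        exclude_observed: bool = False,
                        model: str = "A") -> NullDistribution:
    """Empirical specificity null for a gene panel's SEP association.

    ``expr`` is the full (de-noised) gene-level universe.  ``n_sets`` gene
    sets of ``set_size`` are drawn without replacement from the universe
    (canonically sorted, so draws are reproducible under ``seed`` regardless
    of input row order); by default the observed panel's genes remain part of
    the sampled universe, ``exclude_observed`` removes them.  The observed
    p-value is either supplied or computed from ``observed_genes`` with the
    identical score + model pipeline.
    """
    expr = expr.sort_index()
    universe = expr.index.to_numpy()
    pool = universe
    if exclude_observed and observed_genes is not None:
        pool = np.setdiff1d(universe, np.asarray(observed_genes))
    if set_size > pool.size:
        raise ValueError(
            f"set_size {set_size} exceeds the sampled universe ({pool.size})")
    if observed_p is None and observed_genes is None:
        raise ValueError("provide observed_genes or observed_p")

    samples = analysis_set(meta.loc[expr.columns])
    sub = meta.loc[samples]
    terms = MODEL_LADDER[model]
    used = [c for c in (sep,) + terms if c in sub.columns]
    sub = sub[sub[used].notna().all(axis=1)]
    X = build_design(sub, terms, sep=sep).to_numpy(float)

    ind = _quartile_indicator(expr[sub.index])
    rng = np.random.default_rng(seed)
    sets = np.stack([rng.choice(pool.size, size=set_size, replace=False)
                     for _ in range(n_sets)])
    if exclude_observed and observed_genes is not None:
        # map pool positions back to universe positions
        pos = {g: i for i, g in enumerate(universe)}
        lut = np.array([pos[g] for g in pool])
        sets = lut[sets]
    Y = np.stack([ind[s].sum(axis=0) for s in sets], axis=1)
    betas, pvals = _vector_ols_pvalues(X, Y)

    if observed_p is None:
        rows = [i for i, g in enumerate(universe) if g in set(observed_genes)]
        y_obs = ind[rows].sum(axis=0)
        _, p_obs = _vector_ols_pvalues(X, y_obs[:, None])
        observed_p = float(p_obs[0])
    return NullDistribution(n_sets=n_sets, set_size=set_size,
                            null_p=pvals, null_beta=betas,
                            observed_p=float(observed_p), seed=seed)
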