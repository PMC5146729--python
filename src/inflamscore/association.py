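"""Association models: per-gene SEP tests, the life-course model ladder,
descriptive group comparisons, score correlations, and simulation-based
power.

All models use the fixed reference coding of :mod:`inflamscore.design`
(high/non-manual SEP = 0), so a positive coefficient always means a higher
outcome in the low socioeconomic group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import scores as _scores
from .design import BATCH_FACTORS, MODEL_LADDER, analysis_set, build_design
from .preprocess import _indicator, fit_crossed_mixed_model

logger = logging.getLogger(__name__)

__all__ = ["AssociationResult", "score_association", "life_course_ladder",
           "per_gene_association", "table1", "score_correlations",
           "power_by_simulation", "ols_exposure_test"]


@dataclass
class AssociationResult:
    """One fitted exposure-outcome contrast."""

    outcome: str
    exposure: str
    model: str
    beta: float
    se: float
    pvalue: float
    n: int
    adjustment: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"outcome": self.outcome, "exposure": self.exposure,
                "model": self.model, "beta": self.beta, "se": self.se,
                "pvalue": self.pvalue, "n": self.n,
                "adjustment": ";".join(self.adjustment)}


def ols_exposure_test(X: np.ndarray, y: np.ndarray,
                      col: int = 1) -> tuple[float, float, float]:
    """Least-squares fit of ``y`` on ``X``; t test of coefficient ``col``.

    Returns (beta, se, two-sided p).  Closed-form normal equations; used both
    directly and as the vectorised kernel of the specificity null.
    """
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    sigma2 = resid @ resid / df
    se = float(np.sqrt(sigma2 * XtX_inv[col, col]))
    t = beta[col] / se
    pval = float(2 * stats.t.sf(abs(t), df))
    return float(beta[col]), se, pval


def score_association(score: pd.Series, meta: pd.DataFrame,
                      sep: str = "sep_early", model: str = "A",
                      samples: pd.Index | None = None) -> AssociationResult:
    """Linear model of a composite score on a SEP indicator.

    ``model`` selects the adjustment rung (A-D, fully_adjusted, unadjusted).
    ``samples`` fixes the analysis set; by default the shared complete-case
    set over the whole ladder is used so n does not drift between rungs.
    """
    if model not in MODEL_LADDER:
        raise ValueError(f"unknown model '{model}'")
    terms = MODEL_LADDER[model]
    if samples is None:
        samples = analysis_set(meta)
    sub = meta.loc[meta.index.intersection(samples)]
    used = [c for c in (sep,) + terms if c in sub.columns]
    sub = sub[sub[used].notna().all(axis=1)]
    sub = sub.loc[sub.index.intersection(score.index)]
    missing_terms = [t for t in terms if t not in meta.columns]
    if missing_terms:
        raise ValueError(f"metadata lacks model covariates: {missing_terms}")
    X = build_design(sub, terms, sep=sep)
    y = score.loc[sub.index].to_numpy(float)
    beta, se, p = ols_exposure_test(X.to_numpy(float), y, col=1)
    return AssociationResult(
        outcome=score.name or "score", exposure=sep, model=model,
        beta=beta, se=se, pvalue=p, n=len(sub),
        adjustment=tuple(t for t in terms),
    )


def life_course_ladder(score: pd.Series, meta: pd.DataFrame,
                       sep: str = "sep_early",
                       models: tuple[str, ...] = ("A", "B", "C", "D",
                                                  "fully_adjusted")) -> pd.DataFrame:
    """Fit the sequentially adjusted models on one shared analysis set."""
    samples = analysis_set(meta)
    usable = []
    for m in models:
        if any(t not in meta.columns for t in MODEL_LADDER[m]):
            logger.warning("skipping model %s: missing covariates", m)
            continue
        usable.append(m)
    rows = [score_association(score, meta, sep=sep, model=m,
                              samples=samples).to_dict() for m in usable]
    return pd.DataFrame(rows).set_index("model")


def per_gene_association(expr: pd.DataFrame, meta: pd.DataFrame,
                         sep: str = "sep_early",
                         alpha: float | None = None,
                         factors: tuple[str, ...] = BATCH_FACTORS,
                         reml: bool = True) -> pd.DataFrame:
    """Per-gene mixed-model SEP tests on raw (not de-noised) expression.

    Each gene is fit with the per-gene fixed effects and crossed batch random
    intercepts; the Wald test of the SEP coefficient is reported.  When
    ``alpha`` is omitted the PCA-based effective number of tests of ``expr``
    sets the corrected significance level.  Non-converging genes are flagged
    and excluded from the significance summary.
    """
    meta = meta.loc[expr.columns]
    if alpha is None:
        _, alpha = _scores.effective_tests(expr)
    terms = tuple(t for t in MODEL_LADDER["model1"] if t in meta.columns)
    need = [sep] + list(terms)
    mask = meta[need].notna().all(axis=1).to_numpy()
    sub = meta.loc[mask]
    X = build_design(sub, terms, sep=sep).to_numpy(float)
    usable = [f for f in factors if f in sub.columns
              and sub[f].nunique(dropna=True) >= 2]
    Zs = {f: _indicator(pd.factorize(sub[f])[0]) for f in usable}
    vals = expr.to_numpy(float)[:, mask]
    rows = []
    for g in range(vals.shape[0]):
        try:
            if usable:
                fit = fit_crossed_mixed_model(vals[g], X, Zs, reml=reml)
                beta, se, p, conv = fit.beta, fit.se, fit.pvalue, fit.converged
            else:
                beta, se, p = ols_exposure_test(X, vals[g])
                conv = True
        except (np.linalg.LinAlgError, ValueError):
            beta = se = p = np.nan
            conv = False
        rows.append({"gene_id": expr.index[g], "beta": beta, "se": se,
                     "pvalue": p, "converged": conv, "n": int(mask.sum())})
    out = pd.DataFrame(rows).set_index("gene_id")
    out["significant"] = out["converged"] & (out["pvalue"] < alpha)
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# descriptive statistics


def table1(meta: pd.DataFrame, group: str,
           continuous: tuple[str, ...] = ("age", "bmi", "alcohol"),
           categorical: tuple[str, ...] = ("gender", "bc_case", "nhl_case",
                                           "centre", "phase", "smoking"),
           ) -> pd.DataFrame:
    """Descriptive comparison of a binary grouping variable.

    Continuous variables: per-group mean (SD) and a pooled-variance two-sample
    t test.  Categorical variables: per-group counts (percent) and a
    chi-squared test — with continuity correction for 2x2 tables, without for
    larger tables.  Cells with expected count < 1 annotate a warning but the
    test is still computed.
    """
    g = meta[group].dropna()
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"grouping variable '{group}' must be binary")
    rows = []
    for var in continuous:
        if var not in meta.columns:
            continue
        sub = meta[[var]].join(g.rename("_g")).dropna()
        a = sub.loc[sub["_g"] == levels[0], var]
        b = sub.loc[sub["_g"] == levels[1], var]
        _, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "variable": var, "level": "", "kind": "continuous",
            f"group_{levels[0]}": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
            f"group_{levels[1]}": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
            "pvalue": float(p), "warning": "",
        })
    for var in categorical:
        if var not in meta.columns:
            continue
        sub = meta[[var]].join(g.rename("_g")).dropna()
        tab = pd.crosstab(sub[var], sub["_g"])
        chi2, p, _, expected = stats.chi2_contingency(
            tab.to_numpy(), correction=(tab.shape == (2, 2)))
        warn = "expected cell < 1" if (expected < 1).any() else ""
        for lv in tab.index:
            row = {"variable": var, "level": str(lv), "kind": "categorical",
                   "pvalue": float(p), "warning": warn}
            for grp in levels:
                cnt = int(tab.loc[lv, grp]) if grp in tab.columns else 0
                tot = int(tab[grp].sum()) if grp in tab.columns else 0
                pct = 100 * cnt / tot if tot else 0.0
                row[f"group_{grp}"] = f"{cnt} ({pct:.1f})"
            rows.append(row)
    return pd.DataFrame(rows)


def group_test_categorical(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Chi-squared test with the table-size-dependent correction convention."""
    arr = np.asarray(table)
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=(arr.shape == (2, 2)))
    return float(chi2), float(p)


def score_correlations(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among all score columns.

    Constant columns have undefined correlation and are reported missing.
    """
    if len(score_table) < 3:
        raise ValueError("need at least 3 samples for correlations")
    out = score_table.corr(method="spearman")
    constant = score_table.std(ddof=0) == 0
    out.loc[constant, :] = np.nan
    out.loc[:, constant] = np.nan
    np.fill_diagonal(out.values, np.where(constant, np.nan, 1.0))
    return out


# ---------------------------------------------------------------------------
# power


def power_by_simulation(config_template, effect: float, n_grid: list[int],
                        alpha: float = 0.05, reps: int = 100,
                        seed: int = 0, sep: str = "sep_early",
                        model: str = "A") -> pd.Series:
    """Monte-Carlo power of the composite-score SEP test across sample sizes.

    For each n in ``n_grid``, simulate ``reps`` cohorts from the template
    configuration with the given per-gene effect, compute the quartile score
    over the inflammatory panel, fit the chosen score model, and report the
    fraction of p-values below ``alpha``.
    """
    import dataclasses

    from .annotation import collapse_probes, select_inflammatory
    from .cohort import generate_cohort

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    power = {}
    for n in n_grid:
        hits = 0
        for _ in range(reps):
            cfg = dataclasses.replace(config_template, n_samples=n,
                                      effect_delta=effect,
                                      seed=int(rng.integers(2 ** 31)))
            cohort = generate_cohort(cfg)
            expr = collapse_probes(cohort.expression, cohort.probe_to_gene)
            panel, _ = select_inflammatory(expr, cohort.gene_list)
            score = _scores.quartile_score(panel)
            res = score_association(score, cohort.metadata, sep=sep, model=model)
            hits += res.pvalue < alpha
        power[n] = hits / reps
    return pd.Series(power, name="power")
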