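"""Quantile normalization and mixed-model technical de-noising.

The de-noising model for one gene's log2 expression Y_i is

    Y_i = alpha + beta1 * SEP_i + FE_i beta2 + u_iso(i) + u_hyb(i) + u_lab(i) + e_i

with crossed random intercepts for the RNA isolation, hybridization and
labeling batches, estimated by restricted maximum likelihood.  De-noised
expression subtracts only the predicted random intercepts (BLUPs); fixed
effects stay in the data so downstream score models re-adjust for them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

from .design import BATCH_FACTORS, MODEL_LADDER, build_design

logger = logging.getLogger(__name__)

__all__ = ["quantile_normalize", "denoise", "DenoisedMatrix", "MixedFit",
           "fit_crossed_mixed_model"]


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common reference distribution.

    The reference is the across-sample mean of sorted values.  Ties within a
    column receive the mean of the reference values their ranks span, so the
    result does not depend on input row order.
    """
    if expr.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = expr.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains non-finite values")
    n_rows = vals.shape[0]
    target = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n_rows)
        ranks[order] = np.arange(1, n_rows + 1)
        # average ranks (1-based); ties share the mean of spanned targets
        _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=ranks)
        avg = (sums / counts)[inv]
        lo = np.floor(avg).astype(int) - 1
        hi = np.ceil(avg).astype(int) - 1
        out[:, j] = 0.5 * (target[lo] + target[hi])
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


@dataclass
class MixedFit:
    """Summary of one gene's crossed random-intercept fit."""

    beta: float                     # SEP coefficient (design column 1)
    se: float
    pvalue: float
    vcomp: dict[str, float]         # variance component per batch factor
    scale: float                    # residual variance
    converged: bool
    blups: dict[str, np.ndarray]    # per-level predicted random intercepts


@dataclass
class DenoisedMatrix:
    """A de-noised expression matrix with its provenance."""

    values: pd.DataFrame
    removed_factors: tuple[str, ...]
    fit_log: pd.DataFrame = field(repr=False, default=None)


def _indicator(codes: np.ndarray) -> np.ndarray:
    Z = np.zeros((codes.size, codes.max() + 1))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def fit_crossed_mixed_model(y: np.ndarray, X: np.ndarray,
                            Zs: dict[str, np.ndarray],
                            reml: bool = True,
                            maxiter: int = 200) -> MixedFit:
    """REML fit of a linear model with crossed random intercepts.

    ``Zs`` maps factor name to its sample-by-level indicator matrix.  The
    exposure of interest is assumed to be column 1 of ``X`` (after the
    intercept).  Per-level BLUPs are computed from the estimated variance
    components as  u_f = sigma_f^2 Z_f' V^{-1} (y - X beta).
    """
    names = list(Zs)
    vcs = VCSpec(
        names,
        [[[f"{nm}_{j}" for j in range(Zs[nm].shape[1])]] for nm in names],
        [[Zs[nm]] for nm in names],
    )
    n = y.size
    model = MixedLM(y, X, groups=np.zeros(n), exog_vc=vcs)
    res = None
    # variance components near the boundary defeat individual optimizers;
    # accept the first of a small chain that reports convergence
    for opt in ("bfgs", "lbfgs", "powell"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cand = model.fit(reml=reml, maxiter=maxiter, method=opt)
        res = cand if res is None else res
        if cand.converged:
            res = cand
            break
    converged = bool(getattr(res, "converged", True))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta = float(res.fe_params[1]) if X.shape[1] > 1 else float("nan")
        se = float(res.bse_fe[1]) if X.shape[1] > 1 else float("nan")
        pval = float(res.pvalues[1]) if X.shape[1] > 1 else float("nan")
    vcomp = {nm: float(v) for nm, v in zip(names, res.vcomp)}
    resid = y - X @ res.fe_params
    V = res.scale * np.eye(n)
    for nm in names:
        V += vcomp[nm] * Zs[nm] @ Zs[nm].T
    Vi_r = np.linalg.solve(V, resid)
    blups = {nm: vcomp[nm] * Zs[nm].T @ Vi_r for nm in names}
    return MixedFit(beta=beta, se=se, pvalue=pval, vcomp=vcomp,
                    scale=float(res.scale), converged=converged, blups=blups)


def _centering_prediction(y: np.ndarray, codes: dict[str, np.ndarray]) -> np.ndarray:
    """Sequential batch-mean centering: per factor, the deviation of batch
    means of the current residual from its grand mean."""
    pred = np.zeros_like(y, dtype=float)
    resid = y.astype(float).copy()
    for c in codes.values():
        means = np.bincount(c, weights=resid) / np.bincount(c)
        dev = means[c] - resid.mean()
        pred += dev
        resid -= dev
    return pred


def denoise(expr: pd.DataFrame, meta: pd.DataFrame,
            sep: str = "sep_early",
            factors: tuple[str, ...] = BATCH_FACTORS,
            method: str = "reml",
            reml: bool = True,
            maxiter: int = 200) -> DenoisedMatrix:
    """Remove predicted technical batch intercepts from every gene.

    The fixed-effect part of each fit is the per-gene model (SEP plus age,
    gender, centre, phase and the two case-control indicators, as available
    in ``meta``) restricted to samples with complete covariates; the
    per-level random-intercept predictions are then subtracted for *all*
    samples (batch levels unseen in the fit predict zero).  Genes whose REML
    fit fails or does not converge fall back to sequential batch-mean
    centering (logged).  ``method="centering"`` skips REML entirely.

    Dimensions and gene identities are always preserved.
    """
    usable = [f for f in factors if f in meta.columns
              and meta[f].nunique(dropna=True) >= 2]
    if not usable:
        logger.warning("no batch factor with >=2 levels; returning input unchanged")
        return DenoisedMatrix(values=expr.copy(), removed_factors=(),
                              fit_log=pd.DataFrame(index=expr.index))
    meta = meta.loc[expr.columns]
    codes_all = {f: pd.factorize(meta[f])[0] for f in usable}

    model_terms = tuple(t for t in MODEL_LADDER["model1"] if t in meta.columns)
    sep_col = sep if sep in meta.columns else None
    need = ([sep_col] if sep_col else []) + list(model_terms)
    fit_mask = meta[need].notna().all(axis=1).to_numpy() if need \
        else np.ones(len(meta), bool)
    X_fit = build_design(meta.loc[fit_mask], model_terms, sep=sep_col).to_numpy(float)
    # factor level order must be shared between the fit subset and the full
    # cohort so BLUPs land on the right samples
    levels = {f: pd.factorize(meta[f])[1] for f in usable}
    codes_fit = {f: pd.Categorical(meta.loc[fit_mask, f],
                                   categories=levels[f]).codes for f in usable}
    Zs_fit = {f: _indicator_with_k(codes_fit[f], len(levels[f])) for f in usable}

    vals = expr.to_numpy(float)
    out = vals.copy()
    log_rows = []
    for g in range(vals.shape[0]):
        y = vals[g]
        fit: MixedFit | None = None
        if method == "reml":
            try:
                fit = fit_crossed_mixed_model(y[fit_mask], X_fit, Zs_fit,
                                              reml=reml, maxiter=maxiter)
                if not fit.converged:
                    fit = None
            except (np.linalg.LinAlgError, ValueError):
                fit = None
        if fit is not None:
            pred = np.zeros(len(meta))
            for f in usable:
                pred += fit.blups[f][codes_all[f]]
            out[g] = y - pred
            log_rows.append({"gene_id": expr.index[g], "method": "reml",
                             "converged": True, "scale": fit.scale,
                             **{f"vc_{f}": fit.vcomp[f] for f in usable}})
        else:
            out[g] = y - _centering_prediction(y, codes_all)
            if method == "reml":
                logger.info("gene %s: REML unavailable; batch-mean centering used",
                            expr.index[g])
            log_rows.append({"gene_id": expr.index[g], "method": "centering",
                             "converged": False, "scale": np.nan,
                             **{f"vc_{f}": np.nan for f in usable}})
    fit_log = pd.DataFrame(log_rows).set_index("gene_id")
    return DenoisedMatrix(
        values=pd.DataFrame(out, index=expr.index, columns=expr.columns),
        removed_factors=tuple(usable), fit_log=fit_log,
    )


def _indicator_with_k(codes: np.ndarray, k: int) -> np.ndarray:
    Z = np.zeros((codes.size, k))
    valid = codes >= 0
    Z[np.nonzero(valid)[0], codes[valid]] = 1.0
    return Z
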