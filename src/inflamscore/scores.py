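"""Composite inflammatory-transcriptome scores.

Three per-sample summaries of a gene panel's expression:

* ``quartile_score`` — for each gene, samples strictly above the gene's
  cross-sample 75th percentile contribute 1; the score is the count over the
  panel (integer in [0, G]).
* ``pc1_score`` — the sample coordinate on the first principal component of
  the standardized panel, with a deterministic sign convention.
* ``rank_score`` — a cumulative gene-ranking score: each gene's samples are
  ranked in the direction of that gene's association with a given exposure,
  and a sample's score aggregates its oriented ranks across genes.

Plus the PCA-based effective number of tests used for multiple-testing
correction of the per-gene analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneList

logger = logging.getLogger(__name__)

__all__ = ["quartile_score", "subpathway_scores", "pc1_score", "rank_score",
           "effective_tests", "score_table"]


def quartile_score(expr: pd.DataFrame, q: float = 0.75) -> pd.Series:
    """Count, per sample, the genes expressed strictly above their upper
    quartile.

    Thresholds use the linear-interpolation (type 7) quantile across samples
    and the comparison is strict, so a constant gene contributes 0 everywhere.
    """
    if expr.shape[1] < 4:
        raise ValueError("quartile score needs at least 4 samples")
    vals = expr.to_numpy(float)
    thresholds = np.quantile(vals, q, axis=1, method="linear")
    constant = vals.std(axis=1) == 0
    if constant.any():
        logger.info("%d constant gene(s) contribute 0 to every sample",
                    int(constant.sum()))
    score = (vals > thresholds[:, None]).sum(axis=0)
    return pd.Series(score.astype(int), index=expr.columns, name="quartile_score")


def subpathway_scores(expr: pd.DataFrame, gene_list: GeneList,
                      q: float = 0.75) -> pd.DataFrame:
    """Quartile score restricted to each sub-pathway's gene subset.

    When the sub-pathways partition the scored panel, the row sums equal the
    total quartile score.  An empty sub-pathway yields a zero column (warned).
    """
    cols = {}
    for label in gene_list.subpathway_labels:
        genes = [g for g in gene_list.genes_in_subpathway(label)
                 if g in expr.index]
        if not genes:
            logger.warning("sub-pathway '%s' has no measured gene; zero scores",
                           label)
            cols[label] = pd.Series(0, index=expr.columns)
        else:
            cols[label] = quartile_score(expr.loc[genes], q=q)
    return pd.DataFrame(cols)


def pc1_score(expr: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of the standardized panel.

    Genes (rows) are centred and scaled to unit variance; zero-variance genes
    are dropped with a warning.  The sign is fixed so the sum of gene
    loadings is positive.  Returns the per-sample PC1 coordinates and the
    fraction of total variance PC1 explains.
    """
    if expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValueError("PC1 needs at least 2 genes and 3 samples")
    vals = expr.to_numpy(float)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance gene(s) before PCA",
                       int((~keep).sum()))
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep, None]
    # samples x genes; columns are centred by construction
    U, S, Vt = np.linalg.svd(z.T, full_matrices=False)
    loadings = Vt[0]
    sign = 1.0 if loadings.sum() >= 0 else -1.0
    scores = sign * U[:, 0] * S[0]
    var_explained = float(S[0] ** 2 / (S ** 2).sum())
    return pd.Series(scores, index=expr.columns, name="pc1_score"), var_explained


def rank_score(expr: pd.DataFrame, sep: pd.Series,
               covariates: pd.DataFrame | None = None,
               aggregate: str = "median") -> pd.Series:
    """Cumulative gene-ranking score oriented by per-gene exposure direction.

    Per gene, the direction is the sign of the exposure coefficient from an
    ordinary least-squares fit of expression on the binary exposure (plus
    optional covariates).  Samples are then ranked (average ranks on ties) so
    that change in the low-exposure direction yields a higher rank: ascending
    for up-regulated genes, descending for down-regulated ones.  A sample's
    score is the median (default) or sum of its oriented ranks across genes.
    Genes with an exactly zero coefficient are excluded (logged).  The score
    is exposure-specific and must be recomputed per SEP indicator.
    """
    if aggregate not in ("median", "sum"):
        raise ValueError("aggregate must be 'median' or 'sum'")
    sep = sep.loc[expr.columns]
    mask = sep.notna().to_numpy()
    if sep[mask].nunique() < 2:
        raise ValueError("exposure is constant; per-gene direction undefined")
    parts = [np.ones((int(mask.sum()), 1)), sep[mask].to_numpy(float)[:, None]]
    if covariates is not None:
        parts.append(covariates.loc[expr.columns].to_numpy(float)[mask])
    X = np.hstack(parts)
    Y = expr.to_numpy(float)[:, mask]
    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0][1]
    nonzero = beta != 0
    if not nonzero.any():
        # fully degenerate input (e.g. identical sample columns): every rank
        # is tied, so all samples share the central rank
        logger.warning("every gene has a zero exposure coefficient; "
                       "returning the tied central rank for all samples")
        n = expr.shape[1]
        return pd.Series((n + 1) / 2, index=expr.columns, name="rank_score")
    if not nonzero.all():
        logger.info("excluding %d gene(s) with exactly zero exposure "
                    "coefficient from the rank score", int((~nonzero).sum()))
    vals = expr.to_numpy(float)[nonzero]
    direction = np.sign(beta[nonzero])[:, None]
    ranks = stats.rankdata(vals * direction, axis=1, method="average")
    agg = np.median(ranks, axis=0) if aggregate == "median" else ranks.sum(axis=0)
    return pd.Series(agg, index=expr.columns, name="rank_score")


def effective_tests(expr: pd.DataFrame, variance_target: float = 0.95,
                    alpha: float = 0.05) -> tuple[int, float]:
    """Effective number of tests via PCA of the standardized panel.

    Returns the smallest number of principal components whose cumulative
    variance share reaches ``variance_target``, and the Bonferroni level
    ``alpha`` divided by that count.
    """
    vals = expr.to_numpy(float)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    s = np.linalg.svd(z.T, compute_uv=False)
    share = s ** 2 / (s ** 2).sum()
    k = int(np.searchsorted(np.cumsum(share), variance_target) + 1)
    k = min(k, share.size)
    return k, alpha / k


def score_table(expr: pd.DataFrame, gene_list: GeneList,
                sep: pd.Series | None = None,
                covariates: pd.DataFrame | None = None,
                rank_aggregate: str = "median") -> pd.DataFrame:
    """All composite scores plus the per-sub-pathway scores in one table."""
    panel = expr.loc[[g for g in sorted(set(gene_list.genes)) if g in expr.index]]
    out = quartile_score(panel).to_frame()
    pc1, _ = pc1_score(panel)
    out["pc1_score"] = pc1
    if sep is not None:
        out["rank_score"] = rank_score(panel, sep, covariates,
                                       aggregate=rank_aggregate)
    sub = subpathway_scores(expr, gene_list)
    return pd.concat([out, sub], axis=1)
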