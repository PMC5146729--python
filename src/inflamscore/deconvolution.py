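"""Signature-based cell-type deconvolution of bulk expression.

Implements iterative least-squares deconvolution over a reference signature
matrix: per sample, ordinary least squares on linear-scale intensities,
repeated removal of the most negative cell-type coefficient, and
renormalization of the surviving coefficients to proportions.  Fine-grained
cell types are aggregated to the complete-blood-count classes (Lymphocytes,
Neutrophils, Monocytes) for use as model covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SignatureMatrix", "CellProportions", "estimate_proportions",
           "read_signature"]


@dataclass
class SignatureMatrix:
    """Reference expression profiles (genes x cell types, linear scale)."""

    profiles: pd.DataFrame
    coarse_map: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.profiles.columns) - set(self.coarse_map)
        if missing:
            raise ValueError(f"cell types without a coarse class: {sorted(missing)}")
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("signature profiles must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


@dataclass
class CellProportions:
    """Per-sample cell proportions at fine and coarse resolution."""

    fine: pd.DataFrame      # samples x fine cell types, rows sum to 1
    coarse: pd.DataFrame    # samples x {Lymphocytes, Neutrophils, Monocytes}


def read_signature(profiles_path, coarse_map_path) -> SignatureMatrix:
    profiles = pd.read_csv(profiles_path, sep="\t", index_col=0)
    cmap = pd.read_csv(coarse_map_path, sep="\t", index_col=0).iloc[:, 0].to_dict()
    return SignatureMatrix(profiles=profiles, coarse_map=cmap)


def _deconvolve_sample(S: np.ndarray, y: np.ndarray,
                       types: list[str]) -> dict[str, float]:
    """One sample's iterative least squares with negative-type removal."""
    active = list(range(len(types)))
    while True:
        Sa = S[:, active]
        if np.linalg.matrix_rank(Sa) < len(active):
            bad = [types[j] for j in active]
            raise np.linalg.LinAlgError(
                f"rank-deficient signature over active cell types: {bad}"
            )
        coef, *_ = np.linalg.lstsq(Sa, y, rcond=None)
        if (coef >= 0).all() or len(active) == 1:
            break
        worst = coef.min()
        # tie among equally negative coefficients -> lexicographically first type
        tied = [active[j] for j in range(len(active)) if coef[j] == worst]
        drop = min(tied, key=lambda j: types[j])
        if len(tied) > 1:
            logger.info("negative-coefficient tie; dropping %s", types[drop])
        active.remove(drop)
    coef = np.maximum(coef, 0.0)
    total = coef.sum()
    out = {t: 0.0 for t in types}
    if total > 0:
        for j, a in enumerate(active):
            out[types[a]] = float(coef[j] / total)
    return out


def estimate_proportions(expr: pd.DataFrame,
                         signature: SignatureMatrix) -> CellProportions:
    """Estimate cell-type proportions for every sample of ``expr``.

    ``expr`` is genes x samples.  Deconvolution assumes additive linear-scale
    mixing, so matrices that look log2-scaled (all values below 30) are
    exponentiated first (logged).  Requires at least as many shared signature
    genes as cell types.
    """
    shared = signature.profiles.index.intersection(expr.index)
    k = len(signature.cell_types)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} signature genes shared with the expression "
            f"matrix; need at least {k}"
        )
    sub = expr.loc[shared]
    vals = sub.to_numpy(float)
    if np.nanmax(vals) < 30:
        logger.info("expression looks log2-scaled (max %.2f); exponentiating "
                    "for linear-scale deconvolution", float(np.nanmax(vals)))
        vals = np.exp2(vals)
    S = signature.profiles.loc[shared].to_numpy(float)
    types = signature.cell_types
    rows = [_deconvolve_sample(S, vals[:, i], types) for i in range(vals.shape[1])]
    fine = pd.DataFrame(rows, index=sub.columns)[types]
    coarse = fine.T.groupby(pd.Series(signature.coarse_map)).sum().T
    for cls in ("Lymphocytes", "Neutrophils", "Monocytes"):
        if cls not in coarse.columns:
            coarse[cls] = 0.0
    coarse = coarse[["Lymphocytes", "Neutrophils", "Monocytes"]]
    return CellProportions(fine=fine, coarse=coarse)
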