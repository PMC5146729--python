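"""Fixed-effect design construction shared by the per-gene and score models.

Reference coding is fixed so a positive SEP coefficient always means a higher
outcome in the low socioeconomic group: SEP indicators are 0/1 with the
high/non-manual class at 0; gender reference is "woman", centre reference is
"North", smoking reference is "never", phase reference is phase 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MODEL_LADDER", "BATCH_FACTORS", "build_design", "analysis_set"]

#: crossed technical batch factors removed by de-noising
BATCH_FACTORS = ("batch_isolation", "batch_hybridization", "batch_labeling")

#: sequentially nested life-course adjustment sets.  Model 1 is the per-gene
#: fixed-effect set (the SEP indicator is added separately); A..D add the
#: time-ordered SEP indicators and then behavioural covariates; the fully
#: adjusted model adds estimated neutrophil and monocyte proportions.
_BASE = ("age", "gender", "bc_case", "nhl_case", "phase", "centre")
MODEL_LADDER: dict[str, tuple[str, ...]] = {
    "model1": _BASE,
    "A": _BASE,
    "B": _BASE + ("sep_young",),
    "C": _BASE + ("sep_young", "sep_adult"),
    "D": _BASE + ("sep_young", "sep_adult", "bmi", "smoking", "alcohol"),
    "fully_adjusted": _BASE + ("sep_young", "sep_adult", "bmi", "smoking",
                               "alcohol", "prop_neutrophils", "prop_monocytes"),
    "unadjusted": (),
}

_CATEGORICAL = {
    "gender": ("woman", ["man"]),
    "centre": ("North", ["Central", "South"]),
    "phase": (1, [2]),
    "smoking": ("never", ["former", "current"]),
}


def _encode(meta: pd.DataFrame, term: str) -> pd.DataFrame:
    if term in _CATEGORICAL:
        _, levels = _CATEGORICAL[term]
        cols = {}
        for lv in levels:
            cols[f"{term}[{lv}]"] = (meta[term] == lv).astype(float)
        return pd.DataFrame(cols, index=meta.index)
    return meta[[term]].astype(float)


def build_design(meta: pd.DataFrame, terms: tuple[str, ...] | list[str],
                 sep: str | None = None,
                 drop_aliased: bool = True) -> pd.DataFrame:
    """Build a full-rank design matrix with intercept.

    The SEP indicator (when given) is placed first after the intercept so
    downstream code can address it by name.  Aliased (collinear) columns are
    dropped with a warning.
    """
    parts = [pd.DataFrame({"Intercept": np.ones(len(meta))}, index=meta.index)]
    if sep is not None:
        parts.append(meta[[sep]].astype(float))
    for term in terms:
        if term == sep:
            continue
        parts.append(_encode(meta, term))
    X = pd.concat(parts, axis=1)
    if drop_aliased:
        X = _drop_aliased(X, protect=(sep,) if sep else ())
    return X


def _drop_aliased(X: pd.DataFrame, protect: tuple[str, ...] = ()) -> pd.DataFrame:
    """Drop columns that are linearly dependent on earlier columns."""
    vals = X.to_numpy(float)
    keep: list[int] = []
    for j in range(vals.shape[1]):
        cand = vals[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        elif X.columns[j] in protect:
            raise ValueError(f"protected design column '{X.columns[j]}' is aliased")
        else:
            logger.warning("dropping aliased design column '%s'", X.columns[j])
    return X.iloc[:, keep]


def analysis_set(meta: pd.DataFrame,
                 require: tuple[str, ...] = ("sep_early", "sep_young", "sep_adult",
                                             "bmi", "smoking", "alcohol")) -> pd.Index:
    """Complete-case sample set shared by every rung of the model ladder.

    Fixing one analysis set before fitting keeps n constant across the
    nested models (the study design this emulates reports a single N for the
    whole ladder).
    """
    cols = [c for c in require if c in meta.columns]
    return meta.index[meta[cols].notna().all(axis=1)]
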