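"""Covariate adjustment and adjusted-vs-original network comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .network import WeightedNetwork

logger = logging.getLogger(__name__)


def _design_matrix(cov: pd.DataFrame) -> np.ndarray:
    """Treatment-coded design with intercept; reference = most frequent category.

    Constant or collinear columns are dropped with a warning.
    """
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for c in cov.columns:
        s = cov[c]
        if pd.api.types.is_numeric_dtype(s):
            if s.nunique() < 2:
                logger.warning("covariate %r is constant; dropped", c)
                continue
            cols.append(s.to_numpy(float))
            names.append(c)
        else:
            s = s.astype(str)
            ref = s.value_counts().idxmax()
            for cat in sorted(s.unique()):
                if cat == ref:
                    continue
                cols.append((s == cat).to_numpy(float))
                names.append(f"{c}[{cat}]")
    X = np.column_stack(cols)
    # drop collinear columns by rank-revealing QR (greedy)
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            logger.warning("covariate column %r is collinear; dropped", names[j])
    return X[:, keep]


def adjust_for_covariates(
    data: pd.DataFrame, covariates: list[str], items: list[str] | None = None
) -> pd.DataFrame:
    """Residualize each item on the covariates (complete-case, least squares).

    Returns a DataFrame of residuals with the same item columns.  The
    residuals are continuous, so downstream correlation estimation should use
    Pearson/Spearman rather than polychoric.
    """
    if items is None:
        items = [c for c in data.columns if c not in covariates]
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValidationError(f"covariates not in data: {missing}")
    sub = data[items + covariates].dropna()
    if len(sub) < len(covariates) + 2:
        raise ValidationError("adjust_for_covariates: too few complete-case rows")
    X = _design_matrix(sub[covariates])
    Y = sub[items].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    out = pd.DataFrame(resid, columns=items, index=sub.index)
    out.attrs["n_complete"] = len(sub)
    return out


@dataclass(frozen=True)
class AdjustedComparison:
    """Agreement between an original and a covariate-adjusted network."""

    r_edges: float
    t_stat: float
    p_value: float
    r_ei: float | None
    mean_abs_difference: float
    paired: bool


def compare_adjusted(
    original: WeightedNetwork,
    adjusted: WeightedNetwork,
    paired: bool = True,
) -> AdjustedComparison:
    """Pearson r over upper-triangular edge weights plus a two-sided t-test.

    The t-test is paired over edge weights by default; ``paired=False`` runs
    an independent-samples t-test over the two weight vectors instead.  The
    EI-vector correlation is also reported, since the original analysis is
    ambiguous about which vector it correlated.
    """
    if list(original.labels) != list(adjusted.labels):
        raise ValidationError("compare_adjusted: node labels differ")
    a = original.upper_triangle()
    b = adjusted.upper_triangle()
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    if paired:
        if np.allclose(a, b):
            t, pv = 0.0, 1.0
        else:
            t, pv = stats.ttest_rel(a, b)
    else:
        t, pv = stats.ttest_ind(a, b)
    ei_a = original.weights.sum(axis=1)
    ei_b = adjusted.weights.sum(axis=1)
    r_ei = None
    if np.std(ei_a) > 0 and np.std(ei_b) > 0:
        r_ei = float(np.corrcoef(ei_a, ei_b)[0, 1])
    return AdjustedComparison(
        r_edges=r,
        t_stat=float(t),
        p_value=float(pv),
        r_ei=r_ei,
        mean_abs_difference=float(np.mean(np.abs(a - b))),
        paired=paired,
    )
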