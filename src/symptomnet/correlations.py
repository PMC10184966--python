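"""Correlation matrices for ordinal item data.

Supports Pearson, Spearman and two-step maximum-likelihood polychoric
correlations.  Polychoric estimation assumes each ordinal item discretizes a
latent standard-normal variable: thresholds are set from the marginal
category proportions, then each pairwise latent correlation maximizes the
bivariate-normal orthant likelihood of the observed 2-way table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t

from .errors import ValidationError

logger = logging.getLogger(__name__)

_RHO_BOUND = 0.999


def bivariate_normal_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T.

    Vectorized over ``h`` and ``k`` (broadcast); handles infinite limits.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -_RHO_BOUND, _RHO_BOUND))

    out = np.empty(h.shape, dtype=float)
    hinf_lo = np.isneginf(h) | np.isneginf(k)
    hinf_hi_h = np.isposinf(h)
    hinf_hi_k = np.isposinf(k)
    finite = ~(hinf_lo | hinf_hi_h | hinf_hi_k)

    out[hinf_lo] = 0.0
    # one-sided marginals when the other limit is +inf
    both_hi = hinf_hi_h & hinf_hi_k
    out[hinf_hi_h & ~both_hi] = ndtr(k[hinf_hi_h & ~both_hi])
    out[hinf_hi_k & ~both_hi] = ndtr(h[hinf_hi_k & ~both_hi])
    out[both_hi & ~hinf_lo] = 1.0

    if np.any(finite):
        hf = h[finite].copy()
        kf = k[finite].copy()
        # nudge exact zeros so the Owen's-T arguments stay finite
        hf[hf == 0.0] = 1e-12
        kf[kf == 0.0] = 1e-12
        denom = np.sqrt(1.0 - rho * rho)
        ah = (kf - rho * hf) / (hf * denom)
        ak = (hf - rho * kf) / (kf * denom)
        val = 0.5 * (ndtr(hf) + ndtr(kf)) - owens_t(hf, ah) - owens_t(kf, ak)
        delta = (hf * kf < 0.0) | ((hf * kf == 0.0) & (hf + kf < 0.0))
        val = val - 0.5 * delta
        out[finite] = val
    return np.clip(out, 0.0, 1.0)


def _thresholds_from_margins(counts: np.ndarray) -> np.ndarray:
    """Latent thresholds from marginal category counts (len K -> K-1)."""
    n = counts.sum()
    cum = np.cumsum(counts)[:-1] / n
    with np.errstate(divide="ignore"):
        return ndtri(cum)  # may be +-inf for empty leading/trailing categories


def _cell_probs(th_r: np.ndarray, th_c: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities for all cells of the 2-way table."""
    tr = np.concatenate(([-np.inf], th_r, [np.inf]))
    tc = np.concatenate(([-np.inf], th_c, [np.inf]))
    grid = bivariate_normal_cdf(tr[:, None], tc[None, :], rho)
    pr = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(pr, 1e-12, 1.0)


def polychoric_pair(x, y, levels: int = 4) -> float:
    """Two-step ML polychoric correlation of two ordinal vectors (codes 0..levels-1)."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValidationError("polychoric_pair: length mismatch")
    table = np.bincount(x * levels + y, minlength=levels * levels).reshape(levels, levels)
    return polychoric_from_table(table)


def polychoric_from_table(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.count_nonzero(row) < 2 or np.count_nonzero(col) < 2:
        raise ValidationError("polychoric: a variable is constant in this pair")
    th_r = _thresholds_from_margins(row)
    th_c = _thresholds_from_margins(col)

    def negll(rho):
        return -float(np.sum(table * np.log(_cell_probs(th_r, th_c, rho))))

    res = minimize_scalar(
        negll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


@dataclass
class CorrelationMatrix:
    """A p x p correlation matrix with provenance metadata."""

    values: np.ndarray
    labels: list[str]
    method: str
    n: int
    missing: str = "pairwise"
    psd_repaired: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def nearest_psd(S: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipped PSD repair, rescaled back to unit diagonal."""
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    vals = np.clip(vals, eps, None)
    R = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def correlation_matrix(
    data: pd.DataFrame,
    method: str = "polychoric",
    missing: str = "pairwise",
    items: list[str] | None = None,
) -> CorrelationMatrix:
    """Estimate the item correlation matrix.

    ``missing='pairwise'`` uses pairwise-complete observations,
    ``'complete'`` restricts to complete rows first.  A constant column or an
    item with more than 50% missing raises; non-PSD estimates (possible with
    pairwise deletion or polychorics) are repaired to the nearest PSD matrix
    with unit diagonal and flagged.
    """
    if items is None:
        items = list(data.columns)
    df = data[items]
    if not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
        df = df.apply(pd.to_numeric, errors="coerce")
    if len(df) < 2:
        raise ValidationError("correlation_matrix: need >= 2 observations")
    arr = df.to_numpy(float)
    has_nan = bool(np.isnan(arr).any())
    if has_nan:
        frac_missing = pd.Series(np.isnan(arr).mean(axis=0), index=items)
        bad = frac_missing[frac_missing > 0.5]
        if len(bad):
            raise ValidationError(f"items with >50% missing values: {list(bad.index)}")
    if missing == "complete":
        df = df.dropna()
        arr = df.to_numpy(float)
        has_nan = False
        if len(df) < 2:
            raise ValidationError("correlation_matrix: <2 complete rows")
    elif missing != "pairwise":
        raise ValidationError(f"unknown missing policy {missing!r}")
    stds = np.nanstd(arr, axis=0)
    if np.any(stds < 1e-10):
        const = [items[i] for i in np.flatnonzero(stds < 1e-10)]
        raise ValidationError(f"item {const[0]!r} is constant")

    p = len(items)
    if method == "pearson" and not has_nan:
        R = np.corrcoef(arr.T)
    elif method in ("pearson", "spearman"):
        R = df.corr(method=method).to_numpy()
    elif method == "polychoric":
        arr = df.to_numpy()
        if not np.all(np.isin(arr[~np.isnan(arr)], [0, 1, 2, 3])):
            raise ValidationError("polychoric requires item codes in {0,1,2,3}")
        R = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                mask = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
                R[i, j] = R[j, i] = polychoric_pair(
                    arr[mask, i].astype(int), arr[mask, j].astype(int)
                )
    else:
        raise ValidationError(f"unknown correlation method {method!r}")

    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    repaired = False
    mineig = float(np.linalg.eigvalsh(R).min())
    if mineig < 1e-10:
        logger.info("correlation matrix not PSD (min eig %.3g); repairing", mineig)
        R = nearest_psd(R)
        repaired = True
    n_used = int(len(df))
    return CorrelationMatrix(R, list(items), method, n_used, missing, repaired)
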