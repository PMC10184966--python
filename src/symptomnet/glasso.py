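"""Graphical lasso and EBIC model selection.

Sparse Gaussian graphical model estimation: maximize

    log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |Theta_ij|

over positive-definite precision matrices Theta (the diagonal is not
penalized), via block coordinate descent over columns with an inner lasso
solved by coordinate descent.  Edge weights are the regularized partial
correlations  w_ij = -Theta_ij / sqrt(Theta_ii Theta_jj).

The penalty is selected by minimizing the Extended Bayesian Information
Criterion, EBIC = -2 L + E log n + 4 gamma E log p, where E is the number of
nonzero upper-triangular edges and gamma the extra-penalty hyperparameter.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .correlations import CorrelationMatrix, correlation_matrix
from .errors import ConvergenceError, ValidationError
from .network import EbicTrace, WeightedNetwork

WEIGHT_EPS = 1e-7  # |w| below this is an exact zero


@njit(cache=True)
def _glasso_cd(S, lam, W, B, tol, max_sweeps):  # pragma: no cover - compiled
    p = S.shape[0]
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    beta = np.empty(p - 1)
    idx = np.empty(p - 1, np.int64)
    max_delta = 0.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            m = 0
            for i in range(p):
                if i != j:
                    idx[m] = i
                    m += 1
            for a in range(p - 1):
                ia = idx[a]
                s12[a] = S[ia, j]
                beta[a] = B[ia, j]
                for b in range(p - 1):
                    W11[a, b] = W[ia, idx[b]]
            for _ in range(200):
                d_in = 0.0
                for k in range(p - 1):
                    r = s12[k]
                    for m2 in range(p - 1):
                        if m2 != k:
                            r -= W11[k, m2] * beta[m2]
                    if r > lam:
                        bnew = (r - lam) / W11[k, k]
                    elif r < -lam:
                        bnew = (r + lam) / W11[k, k]
                    else:
                        bnew = 0.0
                    d = abs(bnew - beta[k])
                    if d > d_in:
                        d_in = d
                    beta[k] = bnew
                if d_in < tol * 0.1:
                    break
            for a in range(p - 1):
                ia = idx[a]
                B[ia, j] = beta[a]
                wnew = 0.0
                for b in range(p - 1):
                    wnew += W11[a, b] * beta[b]
                d = abs(wnew - W[ia, j])
                if d > max_delta:
                    max_delta = d
                W[ia, j] = wnew
                W[j, ia] = wnew
        if max_delta < tol:
            return sweep + 1, max_delta, True
    return max_sweeps, max_delta, False


def _theta_from_wb(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    Theta = np.zeros((p, p))
    for j in range(p):
        mask = np.arange(p) != j
        beta = B[mask, j]
        w12 = W[mask, j]
        tjj = 1.0 / (W[j, j] - w12 @ beta)
        Theta[j, j] = tjj
        Theta[mask, j] = -beta * tjj
    return (Theta + Theta.T) / 2.0


def partial_correlations(Theta: np.ndarray) -> np.ndarray:
    """w_ij = -Theta_ij / sqrt(Theta_ii Theta_jj); zero diagonal."""
    d = np.sqrt(np.diag(Theta))
    P = -Theta / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    P[np.abs(P) < WEIGHT_EPS] = 0.0
    return (P + P.T) / 2.0


def glasso(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-7,
    max_sweeps: int = 200,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve one graphical-lasso problem; returns (precision, partial correlations).

    ``lam = 0`` is the unpenalized MLE and is computed by matrix inversion.
    Raises :class:`ConvergenceError` (with a trace) on non-convergence.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError("glasso: S must be square")
    if lam < 0:
        raise ValidationError("glasso: lambda must be >= 0")
    if lam == 0.0:
        Theta = np.linalg.inv(S)
        return Theta, partial_correlations(Theta)
    if warm is not None:
        W, B = warm
    else:
        W, B = S.copy(), np.zeros_like(S)
    sweeps, delta, ok = _glasso_cd(S, float(lam), W, B, tol, max_sweeps)
    if not ok:
        raise ConvergenceError(
            f"glasso did not converge in {max_sweeps} sweeps (last delta {delta:.3g})",
            trace={"sweeps": sweeps, "max_delta": delta, "lambda": lam},
        )
    Theta = _theta_from_wb(W, B)
    return Theta, partial_correlations(Theta)


def penalized_objective(S: np.ndarray, Theta: np.ndarray, lam: float) -> float:
    """The glasso objective (off-diagonal L1 penalty)."""
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return -np.inf
    off = np.abs(Theta).sum() - np.abs(np.diag(Theta)).sum()
    return float(logdet - np.trace(S @ Theta) - lam * off)


def gaussian_loglik(S: np.ndarray, Theta: np.ndarray, n: int) -> float:
    """Profile Gaussian log-likelihood (n/2)(log det Theta - tr(S Theta)).

    Additive constants are dropped; EBIC differences are unaffected.
    """
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.trace(S @ Theta)))


def ebic(loglik: float, E: int, n: int, p: int, gamma: float) -> float:
    """EBIC = -2 L + E log n + 4 gamma E log p."""
    if E < 0 or n <= 0 or p <= 1:
        raise ValidationError("ebic: require E >= 0, n > 0, p > 1")
    return -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def lambda_path(S: np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty path from max|S_ij| down to min_ratio * max|S_ij|."""
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _count_edges(P: np.ndarray) -> int:
    iu = np.triu_indices(P.shape[0], 1)
    return int(np.count_nonzero(P[iu]))


def ebic_glasso(
    data: pd.DataFrame | CorrelationMatrix | np.ndarray,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    cor_method: str = "polychoric",
    missing: str = "pairwise",
    labels: Sequence[str] | None = None,
    communities: dict | None = None,
    tol: float = 1e-7,
    threshold: bool = False,
) -> tuple[WeightedNetwork, EbicTrace]:
    """Fit the glasso path and select the penalty by EBIC.

    ``data`` may be a respondent-by-item DataFrame (a correlation matrix is
    estimated first), a :class:`CorrelationMatrix`, or a raw correlation
    ndarray (``n`` then required).

    ``threshold=True`` additionally zeroes selected edges below
    sqrt(log(p(p-1)/2)/n) — the consistency bound used to suppress the tiny
    spurious edges that EBIC-selected penalties admit in large samples.
    """
    if isinstance(data, pd.DataFrame):
        cm = correlation_matrix(data, method=cor_method, missing=missing)
    elif isinstance(data, CorrelationMatrix):
        cm = data
    else:
        S_arr = np.asarray(data, dtype=float)
        if n is None:
            raise ValidationError("ebic_glasso: n is required with a raw correlation matrix")
        lbl = list(labels) if labels is not None else [f"V{i+1}" for i in range(S_arr.shape[0])]
        cm = CorrelationMatrix(S_arr, lbl, "precomputed", int(n))
    S = cm.values
    n_eff = int(n if n is not None else cm.n)
    p = S.shape[0]
    lams = lambda_path(S, n_lambda, lambda_min_ratio)

    W, B = S.copy(), np.zeros_like(S)
    logliks = np.full(len(lams), np.nan)
    edges = np.zeros(len(lams), dtype=int)
    ebics = np.full(len(lams), np.inf)
    best = None
    failures = []
    for i, lam in enumerate(lams):
        try:
            # warm start from the previous (larger) lambda
            sweeps, delta, ok = _glasso_cd(S, float(lam), W, B, tol, 200)
            if not ok:
                raise ConvergenceError(
                    f"non-convergence at lambda={lam:.4g}",
                    trace={"sweeps": sweeps, "max_delta": delta},
                )
            Theta = _theta_from_wb(W, B)
            P = partial_correlations(Theta)
        except ConvergenceError as e:
            failures.append((lam, e))
            W, B = S.copy(), np.zeros_like(S)  # reset warm state
            continue
        E = _count_edges(P)
        L = gaussian_loglik(S, Theta, n_eff)
        logliks[i] = L
        edges[i] = E
        ebics[i] = ebic(L, E, n_eff, p, gamma)
        if best is None or ebics[i] < ebics[best[0]]:
            best = (i, P)
    if best is None:
        raise ConvergenceError(
            "ebic_glasso: no lambda on the path converged",
            trace={"failures": [(l, str(e)) for l, e in failures]},
        )
    i_best, P_best = best
    if threshold:
        tau = np.sqrt(np.log(p * (p - 1) / 2.0) / n_eff)
        P_best = P_best.copy()
        P_best[np.abs(P_best) < tau] = 0.0
    net = WeightedNetwork(
        P_best,
        cm.labels,
        communities=communities,
        lambda_=float(lams[i_best]),
        gamma=float(gamma),
        ebic=float(ebics[i_best]),
    )
    trace = EbicTrace(lams, logliks, edges, ebics, selected_index=i_best)
    return net, trace
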