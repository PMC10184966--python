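"""Bootstrap accuracy and case-dropping stability diagnostics.

Nonparametric bootstrap of the full estimation pipeline gives per-edge
confidence intervals and edge/centrality difference tests; the case-dropping
(subset) bootstrap yields the correlation-stability (CS) coefficient: the
largest fraction of cases that can be dropped while the subsampled
centrality still correlates >= 0.7 with the full-sample centrality in >= 95%
of subsamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import bridge_expected_influence, expected_influence, strength
from .errors import SymptomNetError
from .glasso import ebic_glasso

logger = logging.getLogger(__name__)

_CENTRALITY_FUNS = {
    "ei": expected_influence,
    "bridge_ei": bridge_expected_influence,
    "strength": strength,
}


@dataclass
class BootstrapResult:
    """Row-resampling bootstrap of the edge weights and EI."""

    labels: list[str]
    edge_index: list[tuple[str, str]]
    observed_edges: np.ndarray           # (n_pairs,)
    edge_samples: np.ndarray             # (B, n_pairs)
    ei_samples: np.ndarray               # (B, p)
    seed: int
    n_failed: int = 0

    @property
    def B(self) -> int:
        return self.edge_samples.shape[0]

    def edge_summary(self, level: float = 0.95) -> pd.DataFrame:
        alpha = (1.0 - level) / 2.0
        lo = np.quantile(self.edge_samples, alpha, axis=0)
        hi = np.quantile(self.edge_samples, 1.0 - alpha, axis=0)
        return pd.DataFrame(
            {
                "node_i": [e[0] for e in self.edge_index],
                "node_j": [e[1] for e in self.edge_index],
                "observed": self.observed_edges,
                "boot_mean": self.edge_samples.mean(axis=0),
                "ci_low": lo,
                "ci_high": hi,
            }
        )

    def _difference_matrix(self, samples: np.ndarray, alpha: float) -> np.ndarray:
        m = samples.shape[1]
        sig = np.zeros((m, m), dtype=bool)
        for i in range(m):
            d = samples[:, i][:, None] - samples[:, i + 1:]
            lo = np.quantile(d, alpha / 2.0, axis=0)
            hi = np.quantile(d, 1.0 - alpha / 2.0, axis=0)
            s = (lo > 0) | (hi < 0)
            sig[i, i + 1:] = s
            sig[i + 1:, i] = s
        return sig

    def edge_difference_test(self, alpha: float = 0.05) -> np.ndarray:
        """Symmetric boolean matrix over edges: bootstrap CI of the pairwise
        difference excludes zero."""
        return self._difference_matrix(self.edge_samples, alpha)

    def centrality_difference_test(self, alpha: float = 0.05) -> np.ndarray:
        return self._difference_matrix(self.ei_samples, alpha)


def bootstrap_edges(
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    communities: dict | None = None,
    max_failure_rate: float = 0.05,
    **fit_kwargs,
) -> BootstrapResult:
    """Resample rows with replacement and re-run the full EBIC-glasso fit.

    Replicates whose estimation fails are skipped and logged; more than
    ``max_failure_rate`` failures aborts.  Deterministic under ``seed``.
    """
    if B < 2:
        raise SymptomNetError("bootstrap_edges: B must be >= 2 (>=100 for quantile CIs)")
    net, _ = ebic_glasso(data, communities=communities, **fit_kwargs)
    item_cols = list(net.labels)
    arr = data[item_cols]
    iu = np.triu_indices(net.p, 1)
    edge_index = [(net.labels[i], net.labels[j]) for i, j in zip(*iu)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    edge_samples = np.empty((B, len(edge_index)))
    ei_samples = np.empty((B, net.p))
    n = len(arr)
    failed = 0
    b = 0
    attempts = 0
    while b < B:
        attempts += 1
        rows = rng.integers(0, n, size=n)
        try:
            bnet, _ = ebic_glasso(arr.iloc[rows], communities=communities, **fit_kwargs)
        except SymptomNetError as e:
            failed += 1
            logger.warning("bootstrap replicate failed: %s", e)
            if failed > max_failure_rate * B:
                raise SymptomNetError(
                    f"bootstrap aborted: {failed} failures in {attempts} attempts"
                ) from e
            continue
        edge_samples[b] = bnet.weights[iu]
        ei_samples[b] = bnet.weights.sum(axis=1)
        b += 1
    return BootstrapResult(
        labels=list(net.labels),
        edge_index=edge_index,
        observed_edges=net.weights[iu],
        edge_samples=edge_samples,
        ei_samples=ei_samples,
        seed=seed,
        n_failed=failed,
    )


@dataclass
class CsResult:
    """Case-dropping bootstrap record and the CS coefficient."""

    statistic: str
    drop_grid: tuple
    correlations: dict = field(default_factory=dict)  # drop -> np.ndarray (B,)
    threshold: float = 0.7
    target: float = 0.95
    seed: int = 0

    def proportion_above(self, threshold: float | None = None) -> pd.Series:
        thr = self.threshold if threshold is None else threshold
        return pd.Series(
            {d: float(np.mean(self.correlations[d] >= thr)) for d in self.drop_grid}
        )

    def cs_coefficient(self, threshold: float | None = None) -> float:
        """Largest drop proportion whose correlations stay >= threshold in
        >= target of subsamples; 0.0 if none does."""
        prop = self.proportion_above(threshold)
        ok = [d for d in self.drop_grid if prop[d] >= self.target]
        return max(ok) if ok else 0.0

    def summary(self) -> pd.DataFrame:
        rows = []
        for d in self.drop_grid:
            c = self.correlations[d]
            rows.append(
                {
                    "drop": d,
                    "mean_correlation": float(np.mean(c)),
                    "prop_above_threshold": float(np.mean(c >= self.threshold)),
                }
            )
        return pd.DataFrame(rows)


def case_drop_cs(
    data: pd.DataFrame,
    statistic: str = "ei",
    drop_grid: tuple = (0.10, 0.25, 0.50, 0.75),
    B: int = 250,
    threshold: float = 0.7,
    target: float = 0.95,
    seed: int = 0,
    communities: dict | None = None,
    **fit_kwargs,
) -> CsResult:
    """Case-dropping (subset) bootstrap for one centrality index.

    For each drop proportion, B subsamples without replacement are re-fitted
    and their centrality correlated (Pearson) with the full-sample
    centrality.  A subsample whose centrality is degenerate (e.g. an empty
    network) contributes correlation 0.
    """
    fun = _CENTRALITY_FUNS.get(statistic)
    if fun is None:
        raise SymptomNetError(f"unknown centrality statistic {statistic!r}")
    if statistic == "bridge_ei" and communities is None:
        raise SymptomNetError("bridge_ei stability requires community labels")
    net, _ = ebic_glasso(data, communities=communities, **fit_kwargs)
    full = fun(net).to_numpy()
    item_cols = list(net.labels)
    arr = data[item_cols]
    n = len(arr)
    if round(n * (1.0 - max(drop_grid))) < 50:
        raise SymptomNetError("case_drop_cs: largest drop leaves fewer than 50 rows")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    result = CsResult(statistic, tuple(drop_grid), threshold=threshold,
                      target=target, seed=seed)
    for d in drop_grid:
        keep = int(round(n * (1.0 - d)))
        cors = np.zeros(B)
        for b in range(B):
            rows = rng.choice(n, size=keep, replace=False)
            try:
                snet, _ = ebic_glasso(arr.iloc[rows], communities=communities, **fit_kwargs)
                sub = fun(snet).to_numpy()
            except SymptomNetError:
                cors[b] = 0.0
                continue
            if np.std(sub) == 0.0 or np.std(full) == 0.0:
                cors[b] = 0.0
            else:
                cors[b] = float(np.corrcoef(full, sub)[0, 1])
        result.correlations[d] = cors
    return result
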