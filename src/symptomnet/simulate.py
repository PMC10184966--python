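"""Synthetic ordinal item data with known network ground truth.

Items are generated from a latent-Gaussian copula: a sparse partial-
correlation structure over 14 latent variables (7 anxiety + 7 sleep) is
inverted to a latent correlation matrix, multivariate-normal draws are
discretized by per-item thresholds into the 0-3 scale of the instruments.
The planted structure (including a few cross-community "bridge" edges) gives
every downstream stage a recoverable ground truth; thresholds default to
category distributions whose means/SDs track the reported item descriptives
(right-skewed anxiety items, left-skewed sleep-timing components).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import ndtr
from scipy.stats import norm

from .errors import SymptomNetError, ValidationError
from .scales import ALL_ITEMS, GAD_ITEMS, PSQI_ITEMS

DEFAULT_COMMUNITIES = {**{c: "anxiety" for c in GAD_ITEMS}, **{c: "sleep" for c in PSQI_ITEMS}}

# Target marginal moments for the default items (mean, SD on the 0-3 scale),
# tracking the published descriptives of each instrument item.
DEFAULT_ITEM_MOMENTS = {
    "gad1": (1.35, 1.07), "gad2": (1.03, 1.05), "gad3": (1.12, 1.01),
    "gad4": (1.03, 1.05), "gad5": (0.77, 0.98), "gad6": (1.07, 1.00),
    "gad7": (0.59, 0.88),
    "psqi1": (1.98, 1.02), "psqi2": (1.99, 1.07), "psqi3": (1.97, 1.21),
    "psqi4": (1.72, 1.27), "psqi5": (1.31, 0.66), "psqi6": (1.09, 1.35),
    "psqi7": (2.12, 0.99),
}

# Default true partial-correlation structure: sparse, predominantly positive,
# two communities with a handful of bridge edges (the strongest bridge is
# gad1-psqi7, mirroring the nervousness <-> daytime-dysfunction link).
DEFAULT_EDGES = [
    # anxiety community
    ("gad1", "gad2", 0.35), ("gad2", "gad3", 0.30), ("gad4", "gad5", 0.30),
    ("gad1", "gad4", 0.22), ("gad3", "gad4", 0.18), ("gad5", "gad6", 0.20),
    ("gad6", "gad7", 0.22), ("gad2", "gad7", 0.15), ("gad1", "gad6", 0.12),
    # sleep community
    ("psqi3", "psqi4", 0.45), ("psqi1", "psqi2", 0.30), ("psqi2", "psqi4", 0.25),
    ("psqi1", "psqi3", 0.20), ("psqi5", "psqi6", 0.15), ("psqi5", "psqi7", 0.18),
    ("psqi1", "psqi5", 0.15), ("psqi2", "psqi6", 0.12),
    # bridges
    ("gad1", "psqi7", 0.16), ("gad1", "psqi1", 0.08), ("gad6", "psqi7", 0.07),
    ("gad6", "psqi6", -0.05),
]

# Covariate category frequencies (independent of the items by default),
# tracking the sample's demographic margins.
COVARIATE_FREQS = {
    "sex": {"Male": 0.3570, "Female": 0.6410, "": 0.0020},
    "age_group": {"Younger adults": 0.6597, "Older adults": 0.3403},
    "education": {
        "Primary school": 0.1180, "Secondary school": 0.1854, "High school": 0.1582,
        "University/College": 0.4707, "Master/Doctorate": 0.0368, "Others": 0.0042,
        "": 0.0260, "Missing-pad": 0.0007,
    },
    "employment": {"Employed": 0.4635, "Retired or unemployed": 0.2358, "Others": 0.3007},
}


@dataclass(frozen=True)
class TrueNetworkSpec:
    """Ground-truth partial-correlation structure for the generator."""

    labels: tuple = tuple(ALL_ITEMS)
    communities: dict = field(default_factory=lambda: dict(DEFAULT_COMMUNITIES))
    edges: tuple = tuple(DEFAULT_EDGES)

    @property
    def p(self) -> int:
        return len(self.labels)

    def with_edge(self, i: str, j: str, weight: float) -> "TrueNetworkSpec":
        """Copy of this spec with edge (i, j) set (or replaced) to ``weight``."""
        key = frozenset((i, j))
        edges = [e for e in self.edges if frozenset(e[:2]) != key]
        if weight != 0.0:
            edges.append((i, j, weight))
        return replace(self, edges=tuple(edges))


@dataclass(frozen=True)
class TrueNetwork:
    """Built ground truth: partial correlations, precision and latent correlation."""

    partial: np.ndarray
    precision: np.ndarray
    latent_correlation: np.ndarray
    labels: tuple
    communities: dict
    shrink_factor: float = 1.0


def build_true_network(
    spec: TrueNetworkSpec, shrink: float = 0.95, max_shrink_iter: int = 50
) -> TrueNetwork:
    """Assemble the precision matrix implied by the planted partial correlations.

    Theta has unit diagonal and Theta_ij = -w_ij; if the requested weights
    break positive-definiteness, off-diagonals are shrunk uniformly by
    ``shrink`` per iteration until PD (the applied factor is recorded).
    """
    labels = list(spec.labels)
    index = {l: i for i, l in enumerate(labels)}
    p = len(labels)
    P = np.zeros((p, p))
    for a, b, w in spec.edges:
        if a not in index or b not in index:
            raise ValidationError(f"edge ({a}, {b}) references unknown node")
        if not -1 < w < 1:
            raise ValidationError(f"edge ({a}, {b}) weight {w} outside (-1, 1)")
        i, j = index[a], index[b]
        P[i, j] = P[j, i] = w
    factor = 1.0
    for _ in range(max_shrink_iter):
        Theta = np.eye(p) - factor * P
        if np.linalg.eigvalsh(Theta).min() > 1e-8:
            break
        factor *= shrink
    else:
        raise SymptomNetError("build_true_network: could not reach positive definiteness")
    Sigma = np.linalg.inv(Theta)
    d = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(d, d)
    np.fill_diagonal(Sigma, 1.0)
    return TrueNetwork(
        partial=factor * P,
        precision=Theta,
        latent_correlation=Sigma,
        labels=tuple(labels),
        communities=dict(spec.communities),
        shrink_factor=factor,
    )


@functools.lru_cache(maxsize=128)
def thresholds_for_moments(mean: float, sd: float) -> tuple:
    """Three latent N(0,1) cutpoints approximating a target 0-3 mean and SD.

    Thresholds are parametrized as center +- spacing and fitted by least
    squares; the calibration is approximate (a normal-threshold model cannot
    reach every mean/SD combination).
    """

    def moments(params):
        c, s = params
        t = np.array([c - s, c, c + s])
        cum = ndtr(t)
        probs = np.diff(np.concatenate(([0.0], cum, [1.0])))
        k = np.arange(4)
        m = float(probs @ k)
        v = float(probs @ (k - m) ** 2)
        return m, np.sqrt(max(v, 1e-12))

    def resid(params):
        m, s_ = moments(params)
        return [m - mean, s_ - sd]

    sol = least_squares(resid, x0=[0.5, 0.9], bounds=([-3.0, 0.05], [3.0, 3.0]))
    c, s = sol.x
    return (c - s, c, c + s)


def default_thresholds(labels=tuple(ALL_ITEMS)) -> dict:
    return {l: thresholds_for_moments(*DEFAULT_ITEM_MOMENTS[l]) for l in labels
            if l in DEFAULT_ITEM_MOMENTS}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to simulate one sample."""

    network: TrueNetworkSpec = field(default_factory=TrueNetworkSpec)
    n: int = 1000
    thresholds: dict | None = None  # label -> 3 increasing cutpoints
    covariates: bool = True
    seed: int = 0

    def resolved_thresholds(self) -> dict:
        th = dict(default_thresholds(self.network.labels))
        th.update(self.thresholds or {})
        for l in self.network.labels:
            t = th.get(l)
            if t is None:
                raise ValidationError(f"no thresholds for item {l!r}")
            if not (t[0] < t[1] < t[2]):
                raise ValidationError(f"thresholds for {l!r} must be strictly increasing")
        return th


def _sample_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    out = {}
    for name, freqs in COVARIATE_FREQS.items():
        cats = list(freqs)
        probs = np.asarray(list(freqs.values()), dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(cats), size=n, p=probs)
        vals = pd.Series([cats[i] for i in draws])
        vals = vals.replace({"": np.nan, "Missing-pad": np.nan})
        out[name] = vals
    return pd.DataFrame(out)


def sample_ordinal(
    config: GeneratorConfig, return_latent: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one sample of ordinal item responses (deterministic under seed).

    Latent multivariate-normal vectors with the spec-implied correlation are
    discretized per item into {0,1,2,3}.  Degenerate (constant) columns are
    flagged in ``df.attrs["degenerate_items"]``.  With ``return_latent=True``
    the continuous latent sample is returned as well.
    """
    if config.n < 1:
        raise ValidationError("sample_ordinal: n must be >= 1")
    truth = build_true_network(config.network)
    th = config.resolved_thresholds()
    ss = np.random.SeedSequence(config.seed)
    item_stream, cov_stream = ss.spawn(2)
    rng = np.random.default_rng(item_stream)
    L = np.linalg.cholesky(truth.latent_correlation)
    Z = rng.standard_normal((config.n, truth.partial.shape[0])) @ L.T
    labels = list(truth.labels)
    data = {}
    for k, l in enumerate(labels):
        cuts = np.asarray(th[l], dtype=float)
        data[l] = np.searchsorted(cuts, Z[:, k]).astype(int)
    df = pd.DataFrame(data)
    if config.covariates:
        cov = _sample_covariates(np.random.default_rng(cov_stream), config.n)
        df = pd.concat([df, cov], axis=1)
    degenerate = [l for l in labels if df[l].nunique() < 2]
    df.attrs["degenerate_items"] = degenerate
    df.attrs["seed"] = config.seed
    if return_latent:
        return df, pd.DataFrame(Z, columns=labels)
    return df


def sample_two_groups(
    config_a: GeneratorConfig, config_b: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent samples for two groups sharing the same node set.

    Substreams are derived from each config's seed so that the draw for one
    group never perturbs the other.
    """
    if tuple(config_a.network.labels) != tuple(config_b.network.labels):
        raise ValidationError("sample_two_groups: node sets differ between groups")
    df_a = sample_ordinal(config_a)
    df_b = sample_ordinal(replace(config_b, seed=config_b.seed + 1_000_003))
    df_a = df_a.copy()
    df_b = df_b.copy()
    df_a["group"] = "a"
    df_b["group"] = "b"
    return df_a, df_b


def category_probabilities(thresholds, sigma_diag: float = 1.0) -> np.ndarray:
    """Normal orthant probabilities implied by a set of 3 cutpoints."""
    t = np.asarray(thresholds, dtype=float)
    cum = norm.cdf(t / np.sqrt(sigma_diag))
    return np.diff(np.concatenate(([0.0], cum, [1.0])))


def write_true_edge_list(truth: TrueNetwork, path) -> None:
    rows = []
    p = len(truth.labels)
    for i in range(p):
        for j in range(i + 1, p):
            w = truth.partial[i, j]
            if w != 0.0:
                rows.append((truth.labels[i], truth.labels[j], w))
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )
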