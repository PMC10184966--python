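"""Container types for estimated symptom networks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .errors import ValidationError


@dataclass
class WeightedNetwork:
    """A symmetric signed partial-correlation network.

    ``weights`` holds regularized partial correlations with a zero diagonal;
    ``communities`` maps each node label to its symptom community
    (e.g. "anxiety" / "sleep").
    """

    weights: np.ndarray
    labels: list[str]
    communities: dict[str, str] | None = None
    lambda_: float | None = None
    gamma: float | None = None
    ebic: float | None = None

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValidationError("weights must be a square matrix")
        if len(self.labels) != W.shape[0]:
            raise ValidationError("labels length must match weight matrix size")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValidationError("weights must be symmetric")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.count_nonzero(self.weights[iu]))

    def upper_triangle(self) -> np.ndarray:
        """Vectorized upper-triangular edge weights (i < j order)."""
        iu = np.triu_indices(self.p, 1)
        return self.weights[iu]

    def community_vector(self) -> np.ndarray:
        if self.communities is None:
            raise ValidationError("network has no community assignment")
        missing = [l for l in self.labels if l not in self.communities]
        if missing:
            raise ValidationError(f"nodes without community assignment: {missing}")
        return np.asarray([self.communities[l] for l in self.labels])

    def edge_frame(self, nonzero_only: bool = True) -> pd.DataFrame:
        """Edge list as a DataFrame with columns node_i, node_j, weight."""
        iu, ju = np.triu_indices(self.p, 1)
        w = self.weights[iu, ju]
        df = pd.DataFrame(
            {
                "node_i": [self.labels[i] for i in iu],
                "node_j": [self.labels[j] for j in ju],
                "weight": w,
            }
        )
        if nonzero_only:
            df = df[df["weight"] != 0.0].reset_index(drop=True)
        return df

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    def to_graph(self) -> nx.Graph:
        """networkx graph with ``weight`` and ``distance`` (1/|w|) edge attrs."""
        G = nx.Graph()
        for l in self.labels:
            G.add_node(l, community=(self.communities or {}).get(l, ""))
        iu, ju = np.triu_indices(self.p, 1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0.0:
                G.add_edge(self.labels[i], self.labels[j], weight=float(w), distance=1.0 / abs(w))
        return G

    def write_edge_list(self, path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


@dataclass
class EbicTrace:
    """Per-lambda fit diagnostics along the regularization path."""

    lambdas: np.ndarray
    loglik: np.ndarray
    edge_counts: np.ndarray
    ebic: np.ndarray
    selected_index: int = field(default=-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "loglik": self.loglik,
                "edges": self.edge_counts,
                "ebic": self.ebic,
                "selected": [i == self.selected_index for i in range(len(self.lambdas))],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
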