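"""Node-importance indices for symptom networks.

Expected influence (EI) is the signed sum of a node's edge weights; bridge
expected influence (bEI) restricts the sum to edges crossing into the other
symptom community.  Strength is the unsigned sum.  Betweenness and closeness
use shortest paths on distances 1/|w|.  Predictability is the in-sample R^2
of regressing each item on its network neighbours.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .errors import ValidationError
from .network import WeightedNetwork


def expected_influence(net: WeightedNetwork, two_step: bool = False) -> pd.Series:
    """One-step EI: EI(v) = sum_u w_vu (signed).  ``two_step`` adds the
    influence of each neighbour's own EI (EI1 + W @ EI1)."""
    ei1 = net.weights.sum(axis=1)
    if two_step:
        ei = ei1 + net.weights @ ei1
    else:
        ei = ei1
    return pd.Series(ei, index=net.labels, name="ei")


def strength(net: WeightedNetwork) -> pd.Series:
    return pd.Series(np.abs(net.weights).sum(axis=1), index=net.labels, name="strength")


def bridge_expected_influence(net: WeightedNetwork) -> pd.Series:
    """bEI(v) = signed sum of v's edge weights to nodes in other communities."""
    comm = net.community_vector()
    cross = comm[:, None] != comm[None, :]
    bei = (net.weights * cross).sum(axis=1)
    return pd.Series(bei, index=net.labels, name="bridge_ei")


def path_centralities(net: WeightedNetwork, harmonic: bool = False) -> pd.DataFrame:
    """Betweenness (pair-count, unnormalized) and closeness on 1/|w| distances.

    Plain closeness is 1 / (sum of distances to reachable nodes), 0 for
    isolated nodes; ``harmonic`` switches to the sum of inverse distances.
    """
    G = net.to_graph()
    btw = nx.betweenness_centrality(G, weight="distance", normalized=False)
    closeness = {}
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="distance"))
    for v in net.labels:
        dists = [d for u, d in lengths.get(v, {}).items() if u != v]
        if harmonic:
            closeness[v] = float(sum(1.0 / d for d in dists))
        else:
            closeness[v] = 0.0 if not dists else float(1.0 / sum(dists))
    return pd.DataFrame(
        {
            "betweenness": pd.Series(btw).reindex(net.labels).fillna(0.0),
            "closeness": pd.Series(closeness).reindex(net.labels),
        }
    )


def predictability(data: pd.DataFrame, net: WeightedNetwork) -> pd.Series:
    """Per-node R^2 from regressing each item on its nonzero-edge neighbours.

    Items are treated as numeric (a nodewise Gaussian approximation of the
    mixed-graphical-model notion of predictability).  Nodes without
    neighbours get R^2 = 0; values are clipped to [0, 1].
    """
    missing = [l for l in net.labels if l not in data.columns]
    if missing:
        raise ValidationError(f"predictability: data lacks items {missing}")
    X = data[net.labels].apply(pd.to_numeric, errors="coerce").dropna().to_numpy(float)
    if X.shape[0] < 3:
        raise ValidationError("predictability: need >= 3 complete rows")
    r2 = {}
    for i, l in enumerate(net.labels):
        nbr = np.flatnonzero(net.weights[i] != 0.0)
        y = X[:, i]
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if nbr.size == 0 or ss_tot == 0.0:
            r2[l] = 0.0
            continue
        A = np.column_stack([np.ones(X.shape[0]), X[:, nbr]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        r2[l] = float(np.clip(1.0 - (resid ** 2).sum() / ss_tot, 0.0, 1.0))
    return pd.Series(r2, name="predictability")


def centrality_table(
    net: WeightedNetwork,
    data: pd.DataFrame | None = None,
    harmonic_closeness: bool = False,
    z_scored: bool = False,
) -> pd.DataFrame:
    """Full per-node table: community, EI, bEI, strength, betweenness,
    closeness and (when data is given) predictability."""
    tab = pd.DataFrame(index=pd.Index(net.labels, name="node"))
    if net.communities is not None:
        tab["community"] = [net.communities[l] for l in net.labels]
    tab["ei"] = expected_influence(net)
    if net.communities is not None:
        tab["bridge_ei"] = bridge_expected_influence(net)
    tab["strength"] = strength(net)
    tab = tab.join(path_centralities(net, harmonic=harmonic_closeness))
    if data is not None:
        tab["predictability"] = predictability(data, net)
    if z_scored:
        num = tab.select_dtypes(float)
        sd = num.std(ddof=1).replace(0.0, np.nan)
        z = (num - num.mean()) / sd
        tab = tab.join(z.add_suffix("_z").fillna(0.0))
    return tab


def rank_symptoms(table: pd.DataFrame, k: int, by: str = "ei") -> list[str]:
    """Top-k node labels by a centrality column; ties broken alphabetically."""
    if table.empty:
        raise ValidationError("rank_symptoms: empty centrality table")
    if by not in table.columns:
        raise ValidationError(f"rank_symptoms: no column {by!r}")
    k = min(max(int(k), 0), len(table))
    s = table[by]
    ranked = sorted(table.index, key=lambda l: (-float(s[l]), str(l)))
    return ranked[:k]
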