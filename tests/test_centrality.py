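"""Centrality indices: EI, bridge EI, path centralities, predictability."""

import itertools

import numpy as np
import pandas as pd
import pytest

from symptomnet.centrality import (
    bridge_expected_influence,
    centrality_table,
    expected_influence,
    path_centralities,
    predictability,
    rank_symptoms,
    strength,
)
from symptomnet.errors import ValidationError
from symptomnet.network import WeightedNetwork
from symptomnet.simulate import GeneratorConfig, sample_ordinal


def _net(weights, labels, communities=None):
    return WeightedNetwork(np.asarray(weights, float), labels, communities=communities)


TRIANGLE = _net(
    [[0, 0.2, 0.3], [0.2, 0, -0.1], [0.3, -0.1, 0]],
    ["a", "b", "c"],
    communities={"a": "x", "b": "x", "c": "y"},
)


def test_triangle_expected_influence_hand_values():
    ei = expected_influence(TRIANGLE)
    assert ei["a"] == pytest.approx(0.5)
    assert ei["b"] == pytest.approx(0.1)
    assert ei["c"] == pytest.approx(0.2)


def test_empty_network_zero_ei():
    net = _net(np.zeros((3, 3)), ["a", "b", "c"])
    assert (expected_influence(net) == 0).all()


def test_adding_positive_edge_increases_ei():
    w = TRIANGLE.weights.copy()
    w[0, 1] += 0.1
    w[1, 0] += 0.1
    bigger = _net(w, TRIANGLE.labels, TRIANGLE.communities)
    assert expected_influence(bigger)["a"] > expected_influence(TRIANGLE)["a"]


def test_ei_linear_in_weights():
    ei1 = expected_influence(TRIANGLE)
    scaled = _net(2.5 * TRIANGLE.weights, TRIANGLE.labels, TRIANGLE.communities)
    assert np.allclose(expected_influence(scaled), 2.5 * ei1)


def test_single_bridge_edge_bei():
    net = _net(
        [[0, 0, 0.16], [0, 0, 0], [0.16, 0, 0]],
        ["gad1", "gad2", "psqi7"],
        communities={"gad1": "anxiety", "gad2": "anxiety", "psqi7": "sleep"},
    )
    bei = bridge_expected_influence(net)
    assert bei["gad1"] == pytest.approx(0.16)
    assert bei["psqi7"] == pytest.approx(0.16)
    assert bei["gad2"] == 0.0


def test_no_cross_community_edges_zero_bei():
    net = _net(
        [[0, 0.4, 0], [0.4, 0, 0], [0, 0, 0]],
        ["a", "b", "c"],
        communities={"a": "x", "b": "x", "c": "y"},
    )
    assert (bridge_expected_influence(net) == 0).all()


def test_partition_identity_machine_precision(default_truth):
    net = WeightedNetwork(default_truth.partial, list(default_truth.labels),
                          communities=default_truth.communities)
    ei = expected_influence(net).to_numpy()
    bei = bridge_expected_influence(net).to_numpy()
    comm = net.community_vector()
    within = ((comm[:, None] == comm[None, :]) * net.weights).sum(axis=1)
    assert np.allclose(bei + within, ei, atol=1e-15)


def test_unassigned_node_errors():
    net = _net(np.zeros((2, 2)), ["a", "b"], communities={"a": "x"})
    with pytest.raises(ValidationError):
        bridge_expected_influence(net)


def _brute_force_paths(net):
    """All-pairs shortest paths by exhaustive simple-path enumeration."""
    labels = net.labels
    p = len(labels)
    dist = {l: {} for l in labels}
    npaths = {l: {} for l in labels}
    through = {l: 0.0 for l in labels}
    adj = {
        (labels[i], labels[j]): 1.0 / abs(net.weights[i, j])
        for i in range(p) for j in range(p)
        if i != j and net.weights[i, j] != 0
    }
    for s_i, t_i in itertools.combinations(range(p), 2):
        s, t = labels[s_i], labels[t_i]
        best, paths = np.inf, []
        nodes = [l for l in labels if l not in (s, t)]
        for r in range(len(nodes) + 1):
            for mid in itertools.permutations(nodes, r):
                seq = (s, *mid, t)
                if all((seq[k], seq[k + 1]) in adj for k in range(len(seq) - 1)):
                    d = sum(adj[(seq[k], seq[k + 1])] for k in range(len(seq) - 1))
                    if d < best - 1e-12:
                        best, paths = d, [seq]
                    elif abs(d - best) <= 1e-12:
                        paths.append(seq)
        if paths:
            dist[s][t] = dist[t][s] = best
            npaths[s][t] = len(paths)
            for seq in paths:
                for v in seq[1:-1]:
                    through[v] += 1.0 / len(paths)
    closeness = {}
    for v in labels:
        ds = list(dist[v].values())
        closeness[v] = 1.0 / sum(ds) if ds else 0.0
    return through, closeness


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_path_centralities_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    p = 6
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < 0.5:
                W[i, j] = W[j, i] = rng.uniform(-0.6, 0.6)
    labels = [f"n{k}" for k in range(p)]
    net = _net(W, labels)
    tab = path_centralities(net)
    btw_bf, clo_bf = _brute_force_paths(net)
    for l in labels:
        assert tab.loc[l, "betweenness"] == pytest.approx(btw_bf[l], abs=1e-9)
        assert tab.loc[l, "closeness"] == pytest.approx(clo_bf[l], abs=1e-9)


def test_star_and_path_betweenness():
    star = _net(
        [[0, 0.5, 0.5, 0.5], [0.5, 0, 0, 0], [0.5, 0, 0, 0], [0.5, 0, 0, 0]],
        ["hub", "l1", "l2", "l3"],
    )
    tab = path_centralities(star)
    assert tab.loc["hub", "betweenness"] == pytest.approx(3.0)  # 3 leaf pairs
    assert (tab.loc[["l1", "l2", "l3"], "betweenness"] == 0).all()
    chain = _net([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]], ["a", "b", "c"])
    assert path_centralities(chain).loc["b", "betweenness"] == pytest.approx(1.0)


def test_predictability_degenerate_cases():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
    # exact linear combination of neighbours
    data["a"] = data["b"] + 2 * data["c"]
    net = _net([[0, 0.3, 0.3], [0.3, 0, 0], [0.3, 0, 0]], ["a", "b", "c"])
    r2 = predictability(data, net)
    assert r2["a"] == pytest.approx(1.0)
    isolated = _net(np.zeros((3, 3)), ["a", "b", "c"])
    assert (predictability(data, isolated) == 0).all()


def test_predictability_near_zero_for_noise():
    rng = np.random.default_rng(1)
    data = pd.DataFrame(rng.normal(size=(2000, 3)), columns=["a", "b", "c"])
    net = _net([[0, 0.3, 0], [0.3, 0, 0.3], [0, 0.3, 0]], ["a", "b", "c"])
    assert predictability(data, net).mean() < 0.01


def test_predictability_matches_analytic_r2(default_truth):
    """On latent Gaussian data the regression R^2 equals 1 - 1/(Theta_ii Sigma_ii)."""
    df, Z = sample_ordinal(GeneratorConfig(n=10000, seed=17, covariates=False),
                           return_latent=True)
    net = WeightedNetwork(default_truth.partial, list(default_truth.labels),
                          communities=default_truth.communities)
    r2 = predictability(Z, net)
    Theta = default_truth.precision
    Sigma = np.linalg.inv(Theta)
    analytic = 1.0 - 1.0 / (np.diag(Theta) * np.diag(Sigma))
    assert np.allclose(r2.to_numpy(), analytic, atol=0.05)


def test_centrality_table_and_ranking(default_truth):
    net = WeightedNetwork(default_truth.partial, list(default_truth.labels),
                          communities=default_truth.communities)
    tab = centrality_table(net)
    assert {"ei", "bridge_ei", "strength", "betweenness", "closeness"} <= set(tab.columns)
    assert np.allclose(tab["strength"], strength(net))
    top = rank_symptoms(tab, 3, by="ei")
    assert len(top) == 3
    assert rank_symptoms(tab, 0) == []
    assert len(rank_symptoms(tab, 99)) == net.p
    # alphabetical tie-break on an all-equal column
    tab2 = tab.copy()
    tab2["ei"] = 1.0
    assert rank_symptoms(tab2, 3, by="ei") == sorted(tab2.index)[:3]
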