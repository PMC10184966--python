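"""Graphical lasso solver and EBIC selection."""

import numpy as np
import pytest
from sklearn.covariance import graphical_lasso as sk_glasso

from symptomnet.errors import ConvergenceError, ValidationError
from symptomnet.glasso import (
    ebic,
    ebic_glasso,
    glasso,
    lambda_path,
    partial_correlations,
    penalized_objective,
)
from symptomnet.simulate import GeneratorConfig, sample_ordinal
from tests.conftest import random_correlation


def test_unpenalized_limit_equals_inversion():
    for seed in range(5):
        S = random_correlation(5, seed)
        _, P0 = glasso(S, 0.0)
        P_inv = partial_correlations(np.linalg.inv(S))
        assert np.allclose(P0, P_inv, atol=1e-6)


def test_empty_network_above_lambda_max():
    S = random_correlation(6, 3)
    lam = np.abs(S - np.diag(np.diag(S))).max()
    _, P = glasso(S, lam + 1e-10)
    assert np.count_nonzero(P) == 0


def test_agrees_with_sklearn_solver():
    """Independent solver cross-check on moderate problems."""
    for seed in (0, 1):
        S = random_correlation(8, seed)
        for lam in (0.05, 0.2):
            Theta, P = glasso(S, lam)
            _, sk_prec = sk_glasso(S, alpha=lam, tol=1e-10, max_iter=500)
            assert np.allclose(Theta, sk_prec, atol=5e-4)


def test_objective_never_below_sklearn():
    S = random_correlation(6, 9)
    lam = 0.1
    Theta, _ = glasso(S, lam)
    _, sk_prec = sk_glasso(S, alpha=lam, tol=1e-10, max_iter=500)
    assert penalized_objective(S, Theta, lam) >= penalized_objective(S, sk_prec, lam) - 1e-7


def test_nonconvergence_raises_with_trace():
    S = random_correlation(6, 5)
    with pytest.raises(ConvergenceError) as ei:
        glasso(S, 0.01, tol=1e-14, max_sweeps=1)
    assert ei.value.trace["sweeps"] == 1


def test_glasso_input_validation():
    with pytest.raises(ValidationError):
        glasso(np.ones((2, 3)), 0.1)
    with pytest.raises(ValidationError):
        glasso(np.eye(3), -0.5)


def test_ebic_formula():
    assert ebic(-50.0, 0, 100, 5, 0.5) == pytest.approx(100.0)
    # gamma = 0 reduces to BIC
    assert ebic(-50.0, 4, 100, 5, 0.0) == pytest.approx(100.0 + 4 * np.log(100))
    expected = 200.0 + 3 * np.log(1000) + 6 * np.log(14)
    assert ebic(-100.0, 3, 1000, 14, 0.5) == pytest.approx(expected)
    with pytest.raises(ValidationError):
        ebic(-1.0, -1, 100, 5, 0.5)


def test_identity_correlation_gives_empty_network():
    net, _ = ebic_glasso(np.eye(6), n=500)
    assert net.edge_count == 0


def test_ebic_trace_contract():
    S = random_correlation(7, 4)
    net, tr = ebic_glasso(S, n=400, n_lambda=25)
    assert np.all(np.diff(tr.lambdas) < 0)
    assert np.all(np.isfinite(tr.ebic))
    assert tr.selected_index == int(np.argmin(tr.ebic))
    assert net.ebic == pytest.approx(tr.ebic[tr.selected_index])
    path = lambda_path(S, 25)
    assert path[0] == pytest.approx(np.abs(S - np.diag(np.diag(S))).max())


def test_raw_matrix_requires_n():
    with pytest.raises(ValidationError):
        ebic_glasso(np.eye(4))


def test_label_equivariance():
    df = sample_ordinal(GeneratorConfig(n=800, seed=13, covariates=False))
    items = [c for c in df.columns if c.startswith(("gad", "psqi"))]
    net1, _ = ebic_glasso(df[items], cor_method="pearson", n_lambda=30)
    perm = list(reversed(items))
    net2, _ = ebic_glasso(df[perm], cor_method="pearson", n_lambda=30)
    W2 = net2.to_frame().loc[items, items].to_numpy()
    assert np.allclose(net1.weights, W2, atol=1e-8)


def test_bridge_edge_detected_in_selected_network():
    """The planted cross-community edge survives EBIC selection."""
    hits = 0
    for seed in range(10):
        df = sample_ordinal(GeneratorConfig(n=5000, seed=seed, covariates=False))
        items = [c for c in df.columns if c.startswith(("gad", "psqi"))]
        net, _ = ebic_glasso(df[items], cor_method="polychoric")
        w = net.to_frame().loc["gad1", "psqi7"]
        hits += w > 0
    assert hits == 10


def test_thresholded_variant_controls_false_edges():
    """At n = 11,000 the consistency-thresholded fit keeps the false-edge
    rate below 10% of absent pairs, and the un-thresholded fit's spurious
    edges are all tiny (an EBIC-at-large-n artefact)."""
    from symptomnet.simulate import TrueNetworkSpec, build_true_network

    truth = build_true_network(TrueNetworkSpec())
    iu = np.triu_indices(14, 1)
    true_nz = truth.partial[iu] != 0
    false_rates = []
    for seed in range(20):
        df = sample_ordinal(GeneratorConfig(n=11000, seed=seed, covariates=False))
        items = [c for c in df.columns if c.startswith(("gad", "psqi"))]
        net_t, _ = ebic_glasso(df[items], cor_method="polychoric", threshold=True)
        w = net_t.weights[iu]
        false_rates.append(((w != 0) & ~true_nz).sum() / (~true_nz).sum())
        if seed < 3:
            net_u, _ = ebic_glasso(df[items], cor_method="polychoric")
            spurious = net_u.weights[iu][(net_u.weights[iu] != 0) & ~true_nz]
            assert np.all(np.abs(spurious) < 0.05)
    assert np.mean(false_rates) < 0.10


def test_edge_count_monotone_in_gamma_quick():
    for seed in range(3):
        df = sample_ordinal(GeneratorConfig(n=700, seed=seed, covariates=False))
        items = [c for c in df.columns if c.startswith(("gad", "psqi"))]
        counts = [
            ebic_glasso(df[items], cor_method="pearson", gamma=g, n_lambda=30)[0].edge_count
            for g in (0.0, 0.5, 1.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]
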