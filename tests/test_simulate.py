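"""Ground-truth network construction and ordinal sampling."""

import numpy as np
import pandas as pd
import pytest

from symptomnet.errors import ValidationError
from symptomnet.simulate import (
    GeneratorConfig,
    TrueNetworkSpec,
    build_true_network,
    category_probabilities,
    default_thresholds,
    sample_ordinal,
    sample_two_groups,
)
from tests.conftest import ANX3


def test_empty_edge_set_gives_identity():
    spec = TrueNetworkSpec(edges=())
    t = build_true_network(spec)
    assert np.allclose(t.precision, np.eye(14))
    assert np.allclose(t.partial, 0.0)
    assert np.allclose(t.latent_correlation, np.eye(14))


def test_two_node_marginal_equals_partial():
    spec = TrueNetworkSpec(
        labels=("gad1", "gad2"),
        communities={"gad1": "anxiety", "gad2": "anxiety"},
        edges=(("gad1", "gad2", 0.4),),
    )
    t = build_true_network(spec)
    assert t.latent_correlation[0, 1] == pytest.approx(0.4)


def test_chain_marginal_is_product_of_partials(chain3_spec):
    t = build_true_network(chain3_spec)
    # brute-force oracle: invert the precision directly
    Theta = np.array([[1, -0.3, 0], [-0.3, 1, -0.2], [0, -0.2, 1.0]])
    Sigma = np.linalg.inv(Theta)
    d = np.sqrt(np.diag(Sigma))
    Sigma = Sigma / np.outer(d, d)
    assert np.allclose(t.latent_correlation, Sigma, atol=1e-12)
    # non-adjacent marginal correlation = product of adjacent partials,
    # scaled by the chain normalization
    assert t.latent_correlation[0, 2] == pytest.approx(Sigma[0, 2])
    assert np.sign(t.latent_correlation[0, 2]) == 1.0


def test_pd_repair_by_shrinkage():
    spec = TrueNetworkSpec(
        labels=("gad1", "gad2", "gad3"),
        communities=dict(ANX3),
        edges=(("gad1", "gad2", 0.9), ("gad2", "gad3", 0.9), ("gad1", "gad3", 0.9)),
    )
    t = build_true_network(spec)
    assert t.shrink_factor < 1.0
    assert np.linalg.eigvalsh(t.precision).min() > 0


def test_invalid_edges_rejected():
    with pytest.raises(ValidationError):
        build_true_network(TrueNetworkSpec(edges=(("gad1", "nope", 0.2),)))
    with pytest.raises(ValidationError):
        build_true_network(TrueNetworkSpec(edges=(("gad1", "gad2", 1.5),)))


def test_with_edge_replaces_and_removes():
    spec = TrueNetworkSpec()
    mod = spec.with_edge("gad1", "psqi7", 0.4)
    assert ("gad1", "psqi7", 0.4) in mod.edges
    assert not any(set(e[:2]) == {"gad1", "psqi7"} and e[2] != 0.4 for e in mod.edges)
    gone = spec.with_edge("gad1", "psqi7", 0.0)
    assert not any(set(e[:2]) == {"gad1", "psqi7"} for e in gone.edges)


def test_sampling_is_deterministic_under_seed():
    cfg = GeneratorConfig(n=200, seed=7)
    a = sample_ordinal(cfg)
    b = sample_ordinal(cfg)
    pd.testing.assert_frame_equal(a, b)


def test_sampling_codes_and_degenerate_flagging():
    cfg = GeneratorConfig(n=300, seed=1, covariates=False,
                          thresholds={"gad1": (-15.0, -14.0, -13.0)})
    df = sample_ordinal(cfg)
    assert set(df["gad2"].unique()) <= {0, 1, 2, 3}
    # thresholds far below the latent range force a constant column
    assert (df["gad1"] == 3).all()
    assert "gad1" in df.attrs["degenerate_items"]


def test_threshold_validation():
    cfg = GeneratorConfig(n=10, thresholds={"gad1": (0.5, 0.5, 1.0)})
    with pytest.raises(ValidationError):
        sample_ordinal(cfg)
    with pytest.raises(ValidationError):
        sample_ordinal(GeneratorConfig(n=0))


def test_marginal_frequencies_match_orthant_probabilities():
    n = 5000
    df = sample_ordinal(GeneratorConfig(n=n, seed=11, covariates=False))
    th = default_thresholds()
    for item in ("gad1", "gad7", "psqi4"):
        probs = category_probabilities(th[item])
        obs = np.bincount(df[item], minlength=4) / n
        # binomial sampling bound: ~4 sigma
        bound = 4.0 * np.sqrt(probs * (1 - probs) / n) + 1e-3
        assert np.all(np.abs(obs - probs) <= bound)


def test_independent_items_have_near_zero_polychorics():
    from symptomnet.correlations import correlation_matrix

    spec = TrueNetworkSpec(edges=())
    df = sample_ordinal(GeneratorConfig(network=spec, n=5000, seed=3, covariates=False))
    cm = correlation_matrix(df[list(spec.labels)], method="polychoric")
    off = cm.values[np.triu_indices(14, 1)]
    assert np.max(np.abs(off)) < 0.05


def test_two_group_sampling_contract():
    cfg = GeneratorConfig(n=120, seed=5)
    a, b = sample_two_groups(cfg, cfg)
    assert (a["group"] == "a").all() and (b["group"] == "b").all()
    # independent draws despite identical configs
    assert not a[["gad1", "psqi1"]].reset_index(drop=True).equals(
        b[["gad1", "psqi1"]].reset_index(drop=True)
    )
    other = GeneratorConfig(network=TrueNetworkSpec(labels=("gad1", "gad2"),
                                                    communities={"gad1": "anxiety",
                                                                 "gad2": "anxiety"},
                                                    edges=()),
                            n=120, seed=5)
    with pytest.raises(ValidationError):
        sample_two_groups(cfg, other)


def test_covariate_margins_roughly_match_targets():
    df = sample_ordinal(GeneratorConfig(n=4000, seed=9))
    frac_female = (df["sex"] == "Female").mean()
    assert frac_female == pytest.approx(0.641, abs=0.03)
    assert df["age_group"].isin(["Younger adults", "Older adults"]).all()
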