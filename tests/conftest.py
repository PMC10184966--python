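import numpy as np
import pytest

from symptomnet.simulate import (
    GeneratorConfig,
    TrueNetworkSpec,
    build_true_network,
    sample_ordinal,
)

ANX3 = {"gad1": "anxiety", "gad2": "anxiety", "gad3": "anxiety"}


@pytest.fixture(scope="session")
def default_truth():
    return build_true_network(TrueNetworkSpec())


@pytest.fixture(scope="session")
def medium_sample():
    """n=1500 sample from the default generator (with covariates)."""
    return sample_ordinal(GeneratorConfig(n=1500, seed=42))


@pytest.fixture(scope="session")
def chain3_spec():
    """Three-node chain gad1 - gad2 - gad3 with known partial correlations."""
    return TrueNetworkSpec(
        labels=("gad1", "gad2", "gad3"),
        communities=dict(ANX3),
        edges=(("gad1", "gad2", 0.3), ("gad2", "gad3", 0.2)),
    )


def random_correlation(p: int, seed: int, strength: float = 1.0) -> np.ndarray:
    """A random well-conditioned correlation matrix."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(p, p + 5)) + strength * rng.normal(size=(p, 1))
    return np.corrcoef(A)
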