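import pytest

from emt import models


@pytest.fixture
def group_only():
    """One scenario-driven group, no ecosystem: (SimulatorSpec, B_true)."""
    return models.group_only_simulator(probs=(0.6, 0.3, 0.1))


@pytest.fixture
def one_group():
    """One group plus a linear-Gaussian abundance metric."""
    return models.one_group_simulator()


@pytest.fixture
def two_group():
    """Two interacting groups plus the abundance metric."""
    return models.two_group_simulator()


@pytest.fixture
def bernoulli_submodel():
    """Factory: a one-node discrete ID with P(U=1) = p."""
    from emt.influence import ChanceNodeSpec, SimulatorSpec, SubmodelSpec, build_parameter_vector

    def make(p):
        spec = SubmodelSpec(
            id="ecosys", role="ecosystem",
            nodes=(ChanceNodeSpec("U", "discrete", domain=(0, 1)),),
            output_metrics=("U",),
        )
        b = build_parameter_vector([spec], {"ecosys": {"U": (1.0 - p, p)}})
        return spec, b

    return make


@pytest.fixture
def gaussian_submodel():
    """Factory: a one-node continuous ID, U ~ Normal(mu, sd), with a
    declared design range."""
    from emt.influence import ChanceNodeSpec, SimulatorSpec, SubmodelSpec, build_parameter_vector

    def make(mu, sd=1.0, rng=(-6.0, 8.0)):
        spec = SubmodelSpec(
            id="ecosys", role="ecosystem",
            nodes=(ChanceNodeSpec("U", "continuous", range=rng),),
            output_metrics=("U",),
        )
        b = build_parameter_vector(
            [spec], {"ecosys": {"U": {"b0": mu, "b": {}, "scale": sd}}}
        )
        return spec, b

    return make
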