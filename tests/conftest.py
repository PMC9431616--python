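import pytest

from rpalme import constraints, solver, synth


@pytest.fixture(scope="session")
def toy_model():
    """Default seeded toy ME model (expression layer on).  Session-scoped
    and shared: tests must copy before mutating."""
    return synth.build_toy_me_model(synth.ToyNetworkConfig(seed=1))


@pytest.fixture(scope="session")
def capped_model(toy_model):
    """Toy model with the succinate photosynthetic ATP cap applied."""
    m = toy_model.copy()
    constraints.apply_atp_cap(m, "succinate")
    return m


@pytest.fixture(scope="session")
def metabolic_model():
    """Expression-free (pure metabolic) variant of the toy network."""
    return synth.build_toy_me_model(
        synth.ToyNetworkConfig(seed=1, include_expression_layer=False))


@pytest.fixture(scope="session")
def succinate_solution(capped_model):
    """Maximal-growth parsimonious solution at succinate uptake 4."""
    return solver.max_growth(capped_model, {"succinate": 4.0}, tol=1e-4)
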