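import pytest

from milkstroke import load_parameter_set, simulate


@pytest.fixture(scope="session")
def paper():
    """The bundled 2023 Japanese baseline parameter set."""
    return load_parameter_set("paper2023")


@pytest.fixture(scope="session")
def result(paper):
    """Full three-scenario simulation of the bundled baseline."""
    return simulate(paper)
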