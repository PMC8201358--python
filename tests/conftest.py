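import pytest

from neuritebool import (
    find_attractors_exhaustive,
    load_neurite_model,
    parse_network,
)


@pytest.fixture(scope="session")
def neurite_net():
    """The bundled 24-node model, inputs completed."""
    return load_neurite_model()


@pytest.fixture(scope="session")
def wt_attractors(neurite_net):
    """Exhaustive synchronous attractor set of the bundled model (2^24 states)."""
    return find_attractors_exhaustive(neurite_net)


@pytest.fixture(scope="session")
def bundled_report(wt_attractors):
    """The full bundled analysis (WT + knockout screen), computed once."""
    from neuritebool import reproduce_analysis

    return reproduce_analysis(wt_set=wt_attractors)


@pytest.fixture
def toggle_net():
    """2-node negative loop: a, !b / b, a."""
    return parse_network("a, !b\nb, a")
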