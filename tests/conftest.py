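import numpy as np
import pytest

from protfun.benchmark import run_recovery
from protfun.ontology import OntologyGraph


@pytest.fixture(scope="session")
def recovery():
    """Full synthetic recovery benchmark, shared across heavy tests."""
    return run_recovery(seed=1)


@pytest.fixture
def chain_graph():
    """R <- A <- C linear chain."""
    return OntologyGraph({"R": set(), "A": {("R", "is_a")},
                          "C": {("A", "is_a")}})


@pytest.fixture
def diamond_graph():
    """A <- {B, C} <- D diamond."""
    return OntologyGraph({
        "A": set(),
        "B": {("A", "is_a")},
        "C": {("A", "is_a")},
        "D": {("B", "is_a"), ("C", "is_a")},
    })


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
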