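import numpy as np
import pytest

from fragverse.config import PipelineConfig
from fragverse.interact import InteractionGraph, PseudoAtom


@pytest.fixture
def config():
    return PipelineConfig()


def make_graph(labels, positions):
    """Build an interaction graph directly from labels and coordinates."""
    return InteractionGraph(
        nodes=[PseudoAtom(np.asarray(p, float), l)
               for l, p in zip(labels, positions)])


def random_graph(rng, max_nodes=5, labels=("A", "B", "C")):
    n = int(rng.integers(0, max_nodes + 1))
    labs = [labels[int(rng.integers(len(labels)))] for _ in range(n)]
    pos = rng.uniform(-5, 5, size=(n, 3))
    return make_graph(labs, pos)


@pytest.fixture
def graph_factory():
    return make_graph
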