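import numpy as np
import pytest

from ggmpath.simulate import figure3_fixture


@pytest.fixture(scope="session")
def fig3():
    """The worked-example control/patient toy graph pair."""
    return figure3_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_graph_pair(rng, n=30, p_edge=0.1, flip=0.3):
    """A random reference graph and a perturbed counterpart on n nodes."""
    from ggmpath.graphs import Graph

    edges1, edges2 = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges1.append((i, j))
                if rng.random() > flip:
                    edges2.append((i, j))
            elif rng.random() < p_edge * flip:
                edges2.append((i, j))
    return Graph(range(n), edges1), Graph(range(n), edges2)
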