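import pytest

from asmcomplexity import Genome, build_graph


@pytest.fixture(scope="session")
def toy_linear():
    """The classic three-node worked example string over {s, a, b}."""
    return Genome("toy", "sababababab", "linear", alphabet=None)


@pytest.fixture(scope="session")
def toy_graph(toy_linear):
    return build_graph(toy_linear, 5)


@pytest.fixture(scope="session")
def interleaved():
    """Two interleaved 2-copy repeats (R and S): the smallest genuinely
    ambiguous circular genome, with exactly two cyclic reconstructions."""
    return Genome("il", "ARBSCRDS", "circular", alphabet=None)


@pytest.fixture
def node_by_seq():
    def find(graph, seq):
        for u in graph.nodes:
            if graph.seq(u) == seq:
                return u
        raise KeyError(seq)
    return find
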