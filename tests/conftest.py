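import numpy as np
import pytest

from netscreen import (
    AnnotationCorpus,
    PPINetwork,
    SeedSet,
    SyntheticConfig,
    generate_benchmark,
)


def make_network(edge_list):
    """Build a PPINetwork from (a, b, score) triples."""
    edges = {}
    for a, b, s in edge_list:
        key = (a, b) if a <= b else (b, a)
        edges[key] = s
    nodes = sorted({g for pair in edges for g in pair})
    return PPINetwork(nodes=nodes, edges=edges)


def random_network(rng, n=20, p=0.3, lo=1, hi=999):
    """Small random weighted graph for property tests (never empty)."""
    names = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((names[i], names[j], int(rng.integers(lo, hi + 1))))
    if not edges:
        edges.append((names[0], names[1], int(rng.integers(lo, hi + 1))))
    return make_network(edges)


@pytest.fixture
def triangle():
    return make_network([("a", "b", 500), ("b", "c", 999), ("a", "c", 10)])


@pytest.fixture
def toy_corpus():
    return AnnotationCorpus(
        terms={"T1": {"a", "b"}, "T2": {"b", "c"}, "T3": {"a", "c"}},
        universe_size=3,
    )


@pytest.fixture(scope="session")
def benchmark_instance():
    """Default synthetic planted-module benchmark, shared across tests."""
    net, corpus, truth = generate_benchmark(SyntheticConfig(master_seed=11))
    return net, corpus, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
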