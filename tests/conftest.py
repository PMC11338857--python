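import math

import pytest

from topoqspr import molgraph, synthetic

#: the thalidomide edge partition as printed in the study's worked example
THALIDOMIDE_PARTITION = {(1, 3): 4, (2, 2): 4, (2, 3): 6, (3, 3): 7}

#: valproic acid heavy-atom skeleton partition, enumerable by hand from
#: (CH3CH2CH2)2CH-COOH: 9 bonds over 10 heavy atoms
VALPROIC_PARTITION = {(1, 2): 2, (2, 2): 2, (2, 3): 2, (1, 3): 2, (3, 3): 1}


@pytest.fixture(scope="session")
def drugs():
    from topoqspr import dataset

    return {rec.name: rec for rec in dataset.load_builtin_drugs()}


@pytest.fixture(scope="session")
def thalidomide(drugs):
    return drugs["Thalidomide"].graph


@pytest.fixture
def k2():
    return molgraph.from_edge_list("a b\n")


@pytest.fixture
def path3():
    return molgraph.from_edge_list("a b\nb c\n")


@pytest.fixture(scope="session")
def random_graphs():
    """200 seeded chemical-like random graphs spanning 5-40 vertices."""
    import numpy as np

    rng = np.random.default_rng(20240808)
    graphs = []
    for _ in range(200):
        n = int(rng.integers(5, 41))
        graphs.append(synthetic.random_molecular_graph(n, 4, seed=int(rng.integers(2**31))))
    return graphs


def brute_force_edge_sum(g, term):
    """Per-edge oracle for the additive indices, bypassing the partition."""
    deg = dict(g.graph.degree)
    return sum(term(*sorted((deg[u], deg[v]))) for u, v in g.graph.edges)
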