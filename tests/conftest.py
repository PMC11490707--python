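import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from traitnets import SiteSpeciesMatrix, TraitTable


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if len(items) <= 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def fixture_graphs() -> dict[str, nx.Graph]:
    """~30 small graphs with known structure: stars, cycles, paths,
    cliques, two-clique bridges, and a few irregular cases."""
    graphs = {}
    for n in (3, 4, 5, 6, 7):
        graphs[f"star{n}"] = nx.star_graph(n - 1)
        graphs[f"cycle{n}"] = nx.cycle_graph(n)
        graphs[f"path{n}"] = nx.path_graph(n)
        graphs[f"clique{n}"] = nx.complete_graph(n)
    for k in (3, 4):
        G = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
        G.add_edge(0, k)
        graphs[f"bridge{k}{k}"] = G
    graphs["empty5"] = nx.empty_graph(5)
    graphs["two_triangles_disjoint"] = nx.disjoint_union(
        nx.complete_graph(3), nx.complete_graph(3))
    graphs["barbell_3_1"] = nx.barbell_graph(3, 1)
    graphs["k4_plus_isolates"] = nx.disjoint_union(nx.complete_graph(4), nx.empty_graph(2))
    graphs["petersen_sub8"] = nx.petersen_graph().subgraph(range(8)).copy()
    return graphs


@pytest.fixture(scope="session")
def graph_suite():
    return fixture_graphs()


@pytest.fixture
def tiny_trait_table() -> TraitTable:
    return TraitTable(values=pd.DataFrame(
        {"size": ["S", "S", "M"], "diet": ["herb", "carn", "carn"]},
        index=["sp1", "sp2", "sp3"],
    ))


@pytest.fixture
def tiny_community() -> SiteSpeciesMatrix:
    return SiteSpeciesMatrix(values=pd.DataFrame(
        [[2.0, 3.0, 5.0], [1.0, 0.0, 1.0]],
        index=["siteA", "siteB"], columns=["sp1", "sp2", "sp3"],
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
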