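import networkx as nx
import pytest

from netconcord.network import InteractionNetwork
from netconcord.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic two-model scenario (seed 11)."""
    return generate_scenario(ScenarioConfig())


@pytest.fixture()
def star7():
    """Star with center C and six leaves L1..L6."""
    edges = [("C", f"L{i}") for i in range(1, 7)]
    return InteractionNetwork.from_edges(edges, name="star7")


@pytest.fixture()
def grid4():
    """4x4 grid graph with string node names R<r>C<c>."""
    g = nx.grid_2d_graph(4, 4)
    edges = [(f"R{a[0]}C{a[1]}", f"R{b[0]}C{b[1]}") for a, b in g.edges]
    return InteractionNetwork.from_edges(edges, name="grid4")


def enumerate_interior_counts(net, seeds):
    """Oracle: count shortest paths through each node by full enumeration.

    Uses networkx all_shortest_paths over every unordered seed pair and
    tallies interior visits; independent of the BFS sigma-product route.
    """
    seeds = sorted(set(seeds))
    covered = {n: 0 for n in net.graph.nodes}
    through = {n: 0 for n in net.graph.nodes}
    for i, s in enumerate(seeds):
        for t in seeds[i + 1:]:
            if not nx.has_path(net.graph, s, t):
                continue
            seen = set()
            for path in nx.all_shortest_paths(net.graph, s, t):
                for v in path[1:-1]:
                    through[v] += 1
                    seen.add(v)
            for v in seen:
                covered[v] += 1
    return covered, through
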