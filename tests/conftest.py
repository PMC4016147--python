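import networkx as nx
import numpy as np
import pandas as pd
import pytest

from roostnet import ColonyConfig, generate_colony


@pytest.fixture(scope="session")
def small_colony():
    """One deterministic synthetic colony-year at study-like scale."""
    return generate_colony(ColonyConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_colony():
    """A fast, few-bat colony for pipeline-level tests."""
    cfg = ColonyConfig(
        n_tagged_bats=8,
        n_untagged_bats=20,
        n_roosts=10,
        tracking_days_per_bat={"mean": 8, "sd": 2, "min": 6, "max": 12},
        fixes_per_night=8,
        seed=5,
    )
    return generate_colony(cfg)


def relocation_table(rows):
    """rows: iterable of (bat_id, iso_date, roost_id)."""
    df = pd.DataFrame(rows, columns=["bat_id", "date", "roost_id"])
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


@pytest.fixture
def two_k4_bridge():
    """Two K4 cliques joined by a single edge (8 nodes)."""
    g = nx.complete_graph(4)
    h = nx.relabel_nodes(nx.complete_graph(4), {i: i + 4 for i in range(4)})
    g = nx.compose(g, h)
    g.add_edge(3, 4)
    return g


def brute_force_bipartition_q(graph):
    """Max modularity over all 2-way partitions (exhaustive)."""
    from roostnet.metrics import modularity_q

    nodes = list(graph.nodes)
    n = len(nodes)
    best = -np.inf
    for mask in range(1, 2 ** (n - 1)):
        a = {nodes[i] for i in range(n) if (mask >> i) & 1}
        b = set(nodes) - a
        best = max(best, modularity_q(graph, [a, b]))
    return best
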