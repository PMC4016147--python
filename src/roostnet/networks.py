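"""Two-mode bat-roost network construction and single-mode projections.

A colony-year's relocation table defines an unweighted bipartite graph:
bats and roosts are the two node sets and an edge joins bat *b* to roost
*r* when *b* was relocated at *r* at least once.  Repeated use collapses to
a single edge (no edge weights, to avoid bias from uneven tracking
periods).  The single-mode projection of the bat nodes is the colony's
social network; the projection of the roost nodes is the roost network
used by the removal simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["BipartiteNetwork", "build_bipartite", "project", "attach_node_attributes"]

BAT_SET, ROOST_SET = 0, 1


@dataclass
class BipartiteNetwork:
    """Unweighted two-mode network of bats and roosts."""

    graph: nx.Graph  # nodes carry bipartite=0 (bats) / 1 (roosts)

    @property
    def bat_nodes(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if d["bipartite"] == BAT_SET}

    @property
    def roost_nodes(self) -> set:
        return {n for n, d in self.graph.nodes(data=True) if d["bipartite"] == ROOST_SET}

    @property
    def n_bats(self) -> int:
        return len(self.bat_nodes)

    @property
    def n_roosts(self) -> int:
        return len(self.roost_nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_bipartite(relocations: pd.DataFrame) -> BipartiteNetwork:
    """Build the two-mode network from a (bat_id, date, roost_id) table.

    Every bat and roost appearing in the table becomes a node; edges are
    unweighted and deduplicated.  Raises ``ValueError`` on an empty table.
    """
    if relocations is None or len(relocations) == 0:
        raise ValueError("no relocations")
    g = nx.Graph()
    bats = pd.unique(relocations["bat_id"])
    roosts = pd.unique(relocations["roost_id"])
    g.add_nodes_from(bats, bipartite=BAT_SET)
    g.add_nodes_from(roosts, bipartite=ROOST_SET)
    pairs = relocations[["bat_id", "roost_id"]].drop_duplicates()
    g.add_edges_from(pairs.itertuples(index=False, name=None))
    return BipartiteNetwork(g)


def project(bipartite: BipartiteNetwork, mode: str) -> nx.Graph:
    """Single-mode projection onto ``mode`` in {"bats", "roosts"}.

    Two same-mode nodes are adjacent iff they share at least one
    opposite-mode neighbour; nodes sharing none are kept as isolates.
    """
    if mode == "bats":
        keep = bipartite.bat_nodes
    elif mode == "roosts":
        keep = bipartite.roost_nodes
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'bats' or 'roosts'")
    # sorted node order keeps downstream float reductions bit-reproducible
    # across processes (set order is hash-randomized)
    return nx.bipartite.projected_graph(bipartite.graph, sorted(keep, key=str))


def attach_node_attributes(
    graph: nx.Graph, table: pd.DataFrame, id_col: str, attrs: list[str]
) -> nx.Graph:
    """Copy columns of *table* onto graph nodes keyed by *id_col* (in place)."""
    idx = table.set_index(id_col)
    for node in graph.nodes:
        if node in idx.index:
            for a in attrs:
                graph.nodes[node][a] = idx.at[node, a]
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edgelist(graph: nx.Graph, path) -> None:
    nx.write_edgelist(graph, path, data=False, delimiter="\t")
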