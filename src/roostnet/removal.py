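"""Roost-loss fragmentation simulations on the roost projection.

Random removal: for each proportion p on a grid, floor(p*n) uniformly
chosen nodes are deleted and the connected components of the remainder
counted (an isolated node is a component), repeated ``n_reps`` times;
the curve reports mean and standard error per proportion.  Targeted
removal deletes the most degree-central node(s), ties broken by smallest
node id.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RemovalCurve",
    "count_components",
    "random_removal_curve",
    "targeted_removal",
]


@dataclass
class RemovalCurve:
    proportions: np.ndarray
    n_removed: np.ndarray
    mean_components: np.ndarray
    se_components: np.ndarray
    n_reps: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "proportion": self.proportions,
                "n_removed": self.n_removed,
                "mean_components": self.mean_components,
                "se_components": self.se_components,
            }
        )


def count_components(graph: nx.Graph) -> int:
    """Connected components, isolates counted individually; empty graph -> 0."""
    return nx.number_connected_components(graph)


def random_removal_curve(
    graph: nx.Graph,
    max_removed_fraction: float = 0.70,
    step: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> RemovalCurve:
    """Mean +/- SE component count under uniform random node removal.

    The proportion grid runs from 0 to ``max_removed_fraction`` in ``step``
    increments; the number removed at proportion p is floor(p * n).
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    if step <= 0:
        raise ValueError("step must be positive")
    nodes = list(graph.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    props = np.round(np.arange(0.0, max_removed_fraction + 1e-9, step), 10)
    n_removed = np.floor(props * n).astype(int)
    means, ses = [], []
    for k in n_removed:
        if k == 0:
            means.append(float(count_components(graph)))
            ses.append(0.0)
            continue
        counts = np.empty(n_reps)
        for r in range(n_reps):
            drop = rng.choice(n, size=k, replace=False)
            keep = [nodes[i] for i in range(n) if i not in set(drop.tolist())]
            counts[r] = count_components(graph.subgraph(keep))
        means.append(float(counts.mean()))
        ses.append(float(counts.std(ddof=1) / np.sqrt(n_reps)))
    return RemovalCurve(
        proportions=props,
        n_removed=n_removed,
        mean_components=np.asarray(means),
        se_components=np.asarray(ses),
        n_reps=n_reps,
    )


def targeted_removal(graph: nx.Graph, k: int = 1) -> tuple[list, int]:
    """Remove the k most degree-central nodes; ties broken by smallest id.

    Returns (removed node ids, component count of the remainder).
    """
    n = graph.number_of_nodes()
    if n < 1:
        raise ValueError("graph has no nodes")
    if k >= n:
        raise ValueError("k must be smaller than the number of nodes")
    ranked = sorted(graph.degree, key=lambda t: (-t[1], str(t[0])))
    removed = [node for node, _ in ranked[:k]]
    remainder = graph.subgraph(set(graph.nodes) - set(removed))
    return removed, count_components(remainder)
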