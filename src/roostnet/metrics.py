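"""Network metric suite for roost (two-mode) and social (single-mode) networks.

Single-mode metrics follow the usual conventions: density 2L/(n(n-1)),
Freeman degree centralization, Watts-Strogatz mean local clustering over
nodes of degree >= 2, mean geodesic distance over connected pairs, and
Newman nominal assortativity ("homophily") over a categorical node
attribute.

Two-mode metrics treat the bipartite graph directly: density L/(n1*n2),
degree centralization normalized by the star maximum attainable at the
same dimensions, and the 4-path (Opsahl) clustering coefficient.

Community structure uses leading-eigenvector modularity: recursive
spectral bisection on the (generalized) modularity matrix, with the
Kernighan-Lin style single-node fine-tuning sweep applied to each
bisection, accepting a split only when it increases Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .networks import BipartiteNetwork

__all__ = [
    "MetricReport",
    "density",
    "density_two_mode",
    "mean_degree",
    "degree_centralization",
    "degree_centralization_two_mode",
    "clustering",
    "clustering_two_mode",
    "modularity_q",
    "modularity_leading_eigenvector",
    "mean_shortest_path",
    "nominal_assortativity",
    "roost_network_report",
    "social_network_report",
]


# ---------------------------------------------------------------------------
# density and degree


def density(graph: nx.Graph) -> float:
    """Single-mode density 2L/(n(n-1))."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("density needs >= 2 nodes")
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def density_two_mode(bnet: BipartiteNetwork) -> float:
    """Two-mode density L/(n_bats * n_roosts)."""
    if bnet.n_bats == 0 or bnet.n_roosts == 0:
        raise ValueError("both node sets must be non-empty")
    return bnet.n_edges / (bnet.n_bats * bnet.n_roosts)


def mean_degree(graph: nx.Graph, node_set=None) -> float:
    """Mean degree over *node_set* (default: all nodes)."""
    nodes = list(graph.nodes) if node_set is None else list(node_set)
    if not nodes:
        raise ValueError("empty node set")
    return float(np.mean([graph.degree(n) for n in nodes]))


# ---------------------------------------------------------------------------
# centralization


def degree_centralization(graph: nx.Graph) -> float:
    """Freeman degree centralization: sum(dmax - d_i) / ((n-1)(n-2))."""
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("degree centralization needs >= 3 nodes")
    deg = np.array([d for _, d in graph.degree()], dtype=float)
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def two_mode_centralization_max(n1: int, n2: int) -> float:
    """Maximum of sum(dmax - d_i) over bipartite graphs with set sizes n1, n2.

    Attained by a star whose hub sits in the smaller set (hub degree
    max(n1, n2)): sum over nodes of (dmax - d_i) = (n1+n2)*dmax - 2L is
    maximized by dmax = max(n1, n2) with the minimal L = dmax realizing it.
    """
    m = max(n1, n2)
    return float(m * (n1 + n2 - 2))


def degree_centralization_two_mode(bnet: BipartiteNetwork) -> float:
    """Two-mode degree centralization, star-normalized at the same dimensions."""
    n1, n2 = bnet.n_bats, bnet.n_roosts
    if n1 < 2 or n2 < 2:
        raise ValueError("two-mode centralization needs both sets >= 2")
    deg = np.array([d for _, d in bnet.graph.degree()], dtype=float)
    return float((deg.max() - deg).sum() / two_mode_centralization_max(n1, n2))


# ---------------------------------------------------------------------------
# clustering


def clustering(graph: nx.Graph) -> float:
    """Mean Watts-Strogatz local clustering over nodes with degree >= 2."""
    if graph.number_of_nodes() < 3:
        raise ValueError("clustering needs >= 3 nodes")
    eligible = [n for n, d in graph.degree() if d >= 2]
    if not eligible:
        warnings.warn("no nodes with degree >= 2; clustering defined as 0", stacklevel=2)
        return 0.0
    local = nx.clustering(graph, eligible)
    return float(np.mean(list(local.values())))


def clustering_two_mode(bnet: BipartiteNetwork, primary: str = "roosts") -> float:
    """Two-mode (4-path) clustering coefficient.

    A 4-path is i-a-j-b-k with i, j, k distinct nodes of the *primary* set
    and a != b in the opposite set; it is closed when the end nodes i and k
    share at least one opposite-set neighbour.  Returns closed / total.
    """
    g = bnet.graph
    prim = bnet.roost_nodes if primary == "roosts" else bnet.bat_nodes
    nbrs = {n: set(g.neighbors(n)) for n in g.nodes}
    total = closed = 0
    for j in prim:
        secs = list(nbrs[j])
        for a in secs:
            ia = nbrs[a] - {j}
            for b in secs:
                if b == a:
                    continue
                kb = nbrs[b] - {j}
                for i in ia:
                    for k in kb:
                        if i == k:
                            continue
                        total += 1
                        if nbrs[i] & nbrs[k]:
                            closed += 1
    if total == 0:
        warnings.warn("no 4-paths; two-mode clustering defined as 0", stacklevel=2)
        return 0.0
    return closed / total


# ---------------------------------------------------------------------------
# modularity (leading eigenvector)


def modularity_q(graph: nx.Graph, partition: list[set]) -> float:
    """Q = sum_c (e_cc - a_c^2) for a given node partition."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    member = {}
    for c, nodes in enumerate(partition):
        for n in nodes:
            member[n] = c
    ncom = len(partition)
    e = np.zeros(ncom)  # within-community edge fraction
    a = np.zeros(ncom)  # community degree fraction
    for u, v in graph.edges:
        if member[u] == member[v]:
            e[member[u]] += 1.0
    for n, d in graph.degree():
        a[member[n]] += d
    e /= m
    a /= 2.0 * m
    return float(np.sum(e - a**2))


def _kl_refine(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style single-node fine-tuning of a bisection vector.

    Repeated passes; in each pass every node is flipped exactly once in
    greedy order of gain in s^T Bg s, and the best intermediate state of
    the pass is kept.  Stops when a full pass yields no improvement.
    """
    n = len(s)
    s = s.copy()
    f = float(s @ Bg @ s)
    while True:
        moved = np.zeros(n, dtype=bool)
        trial = s.copy()
        Bs = Bg @ trial
        states = []
        cum = 0.0
        for _ in range(n):
            gains = -4.0 * trial * Bs + 4.0 * np.diag(Bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            cum += gains[i]
            trial[i] = -trial[i]
            Bs += 2.0 * trial[i] * Bg[:, i]
            moved[i] = True
            states.append((cum, trial.copy()))
        best_cum, best_state = max(states, key=lambda t: t[0])
        if best_cum > 1e-12:
            s = best_state
            f += best_cum
        else:
            return s


def modularity_leading_eigenvector(
    graph: nx.Graph, max_communities: int | None = None
) -> tuple[float, list[set]]:
    """Leading-eigenvector community detection.

    Recursively bisects communities along the leading eigenvector of the
    generalized modularity matrix, fine-tunes each bisection with
    single-node sweeps, and accepts a split only if it increases Q.
    Returns (Q, partition).  ``max_communities`` caps the number of
    communities (2 restricts to a single bisection).
    """
    if graph.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    A = nx.to_numpy_array(graph, nodelist=nodes)
    k = A.sum(axis=1)
    two_m = k.sum()
    B = A - np.outer(k, k) / two_m

    partition: list[np.ndarray] = []
    stack = [np.arange(len(nodes))]
    while stack:
        g = stack.pop()
        if len(g) < 2 or (
            max_communities is not None
            and len(partition) + len(stack) + 1 >= max_communities
        ):
            partition.append(g)
            continue
        Bg = B[np.ix_(g, g)]
        Bg = Bg - np.diag(Bg.sum(axis=1))
        vals, vecs = np.linalg.eigh(Bg)
        if vals[-1] <= 1e-12:
            # rows of Bg sum to zero, so lambda_max >= 0 always; equality
            # means s^T Bg s <= 0 for every s: indivisible.
            partition.append(g)
            continue
        s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
        s = _kl_refine(Bg, s)
        dq = float(s @ Bg @ s) / (2.0 * two_m)
        if dq <= 1e-12 or np.all(s > 0) or np.all(s < 0):
            partition.append(g)
            continue
        stack.append(g[s > 0])
        stack.append(g[s < 0])
    parts = [set(nodes[i] for i in g) for g in partition]
    return modularity_q(graph, parts), parts


# ---------------------------------------------------------------------------
# paths and homophily


def mean_shortest_path(graph: nx.Graph, return_excluded: bool = False):
    """Mean geodesic distance over connected unordered node pairs.

    Pairs in different components are excluded; their count is available
    via ``return_excluded=True``.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("mean shortest path needs >= 2 nodes")
    total = 0.0
    pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    pairs //= 2  # ordered -> unordered
    total /= 2.0
    if pairs == 0:
        raise ValueError("no connected node pair")
    excluded = n * (n - 1) // 2 - pairs
    mean = total / pairs
    return (mean, excluded) if return_excluded else mean


def nominal_assortativity(graph: nx.Graph, attribute: str) -> float:
    """Newman nominal assortativity r over a categorical node attribute.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) on the edge
    mixing matrix; in [-1, 1].  Raises when fewer than two attribute
    classes occur among edge endpoints.
    """
    classes = sorted({graph.nodes[u][attribute] for e in graph.edges for u in e})
    if len(classes) < 2:
        raise ValueError("homophily undefined: fewer than two classes among endpoints")
    idx = {c: i for i, c in enumerate(classes)}
    e = np.zeros((len(classes), len(classes)))
    for u, v in graph.edges:
        i, j = idx[graph.nodes[u][attribute]], idx[graph.nodes[v][attribute]]
        e[i, j] += 1.0
        e[j, i] += 1.0
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    ab = float(a @ b)
    if ab == 1.0:
        raise ValueError("homophily undefined: degenerate mixing matrix")
    return float((np.trace(e) - ab) / (1.0 - ab))


# ---------------------------------------------------------------------------
# report containers


@dataclass
class MetricReport:
    """One network's metric row (full precision; round for display)."""

    network_id: str
    n_nodes: int
    n_edges: int
    mean_degree: float
    density: float
    clustering: float
    degree_centralization: float
    modularity_Q: float | None = None
    communities: list[set] | None = None
    mean_shortest_path: float | None = None
    homophily_r: float | None = None
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "network_id": self.network_id,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": round(self.mean_degree, 2),
            "density": round(self.density, 2),
            "clustering": round(self.clustering, 2),
            "degree_centralization": round(self.degree_centralization, 2),
        }
        if self.modularity_Q is not None:
            row["modularity_Q"] = round(self.modularity_Q, 2)
        if self.mean_shortest_path is not None:
            row["mean_shortest_path"] = round(self.mean_shortest_path, 2)
        if self.homophily_r is not None:
            row["homophily_r"] = round(self.homophily_r, 2)
        row.update(self.extra)
        return row


def roost_network_report(bnet: BipartiteNetwork, network_id: str = "roost") -> MetricReport:
    """Two-mode metric row: roost-side mean degree, density, 4-path
    clustering and star-normalized centralization."""
    return MetricReport(
        network_id=network_id,
        n_nodes=bnet.n_bats + bnet.n_roosts,
        n_edges=bnet.n_edges,
        mean_degree=mean_degree(bnet.graph, bnet.roost_nodes),
        density=density_two_mode(bnet),
        clustering=clustering_two_mode(bnet),
        degree_centralization=degree_centralization_two_mode(bnet),
        extra={"n_bats": bnet.n_bats, "n_roosts": bnet.n_roosts},
    )


def social_network_report(
    graph: nx.Graph, attribute: str | None = "age_class", network_id: str = "social"
) -> MetricReport:
    """Single-mode (social) metric row including modularity, mean geodesic
    distance and age-class homophily (None where undefined)."""
    q = parts = None
    if graph.number_of_edges() > 0:
        q, parts = modularity_leading_eigenvector(graph)
    homophily = None
    if attribute is not None:
        try:
            homophily = nominal_assortativity(graph, attribute)
        except (ValueError, KeyError):
            homophily = None
    try:
        msp = mean_shortest_path(graph)
    except ValueError:
        msp = None
    return MetricReport(
        network_id=network_id,
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        mean_degree=mean_degree(graph),
        density=density(graph),
        clustering=clustering(graph),
        degree_centralization=degree_centralization(graph),
        modularity_Q=q,
        communities=parts,
        mean_shortest_path=msp,
        homophily_r=homophily,
    )
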