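"""Erdos-Renyi null models and Monte Carlo permutation tests.

Observed network metrics are compared against metrics of random graphs
with the same node counts and a constant link probability (G(n, p); the
bipartite analogue for two-mode networks).  By default p is matched to the
observed network's density, the only study-derived constant available.

P-values use the add-one Monte Carlo estimator: with N null draws and b
exceedances (ties counted as exceedances), the tail p is (b+1)/(N+1), so
the smallest attainable value with N=500 is 1/501 ~ 0.002.  The reported
value is the smaller tail's p together with its direction; an optional
doubled two-tailed variant is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np

from .networks import BAT_SET, ROOST_SET, BipartiteNetwork

__all__ = [
    "ERConfig",
    "NullTestResult",
    "sample_er_graph",
    "sample_er_bipartite",
    "monte_carlo_test",
    "run_null_suite",
]


@dataclass(frozen=True)
class ERConfig:
    """Size/probability specification for the ER null ensemble."""

    n_nodes: int | None = None              # single-mode
    n_bats: int | None = None               # two-mode
    n_roosts: int | None = None
    link_prob: float | None = None          # None -> match observed density
    n_sims: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.link_prob is not None and not (0.0 <= self.link_prob <= 1.0):
            raise ValueError("link_prob must be in [0, 1]")
        # node counts may be omitted: the null suite matches them to the
        # observed network


@dataclass
class NullTestResult:
    """Observed metric vs. its ER null distribution."""

    metric_name: str
    observed: float
    null_values: np.ndarray
    direction: str   # ">", "<" or "="
    p_value: float
    n_resampled: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if len(self.null_values) > 1 else 0.0

    def as_row(self) -> dict:
        return {
            "metric": self.metric_name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "direction": self.direction,
            "p_value": self.p_value,
            "n_sims": len(self.null_values),
            "n_resampled": self.n_resampled,
        }


def sample_er_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """G(n, p): every unordered node pair is an edge independently w.p. p."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    return g


def sample_er_bipartite(
    n_bats: int, n_roosts: int, p: float, rng: np.random.Generator
) -> BipartiteNetwork:
    """Bipartite G(n1, n2, p) with the package's two-mode container."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    g = nx.Graph()
    bats = [f"b{i}" for i in range(n_bats)]
    roosts = [f"r{j}" for j in range(n_roosts)]
    g.add_nodes_from(bats, bipartite=BAT_SET)
    g.add_nodes_from(roosts, bipartite=ROOST_SET)
    mask = rng.random((n_bats, n_roosts)) < p
    bi, rj = np.nonzero(mask)
    g.add_edges_from((bats[i], roosts[j]) for i, j in zip(bi, rj))
    return BipartiteNetwork(g)


def monte_carlo_test(
    observed: float, null_values: np.ndarray, two_tailed: bool = False
) -> tuple[str, float]:
    """Add-one Monte Carlo permutation test against a null sample.

    Returns (direction, p).  Direction is ">" when the upper tail is the
    smaller one (observed above the null bulk), "<" for the lower tail,
    "=" when the tails are equal.  With ``two_tailed=True`` the smaller
    tail p is doubled (capped at 1).
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0 or not np.all(np.isfinite(null_values)):
        raise ValueError("null_values must be non-empty and finite")
    if not np.isfinite(observed):
        raise ValueError("observed metric is not finite")
    n = null_values.size
    p_up = (np.sum(null_values >= observed) + 1) / (n + 1)
    p_lo = (np.sum(null_values <= observed) + 1) / (n + 1)
    if p_up < p_lo:
        direction, p = ">", p_up
    elif p_lo < p_up:
        direction, p = "<", p_lo
    else:
        direction, p = "=", min(1.0, p_up)
    if two_tailed:
        p = min(1.0, 2.0 * p)
    return direction, float(p)


def run_null_suite(
    network,
    metrics: dict[str, Callable],
    config: ERConfig,
    two_tailed: bool = False,
    max_resample: int = 1000,
) -> list[NullTestResult]:
    """Compare observed metrics to a shared ensemble of ER null networks.

    *network* is an ``nx.Graph`` (single-mode) or ``BipartiteNetwork``;
    *metrics* maps metric names to callables of the network.  A null draw
    on which some metric is incomputable (e.g. homophily with one class)
    is resampled, keeping the ensemble size at ``config.n_sims``; the
    number of resampled draws is recorded per metric.
    """
    config.validate()
    two_mode = isinstance(network, BipartiteNetwork)
    if config.link_prob is not None:
        p = config.link_prob
    else:
        from .metrics import density, density_two_mode

        p = density_two_mode(network) if two_mode else density(network)

    observed = {name: float(fn(network)) for name, fn in metrics.items()}
    rng = np.random.default_rng(config.seed)
    nulls: dict[str, list[float]] = {name: [] for name in metrics}
    resampled = dict.fromkeys(metrics, 0)

    if two_mode:
        nb = config.n_bats if config.n_bats is not None else network.n_bats
        nr = config.n_roosts if config.n_roosts is not None else network.n_roosts
        attr_source = None
    else:
        nn = config.n_nodes if config.n_nodes is not None else network.number_of_nodes()
        # carry observed node attributes onto null nodes so attribute
        # metrics (homophily) are computable on null draws
        attr_source = [dict(network.nodes[v]) for v in network.nodes]

    def _draw():
        if two_mode:
            return sample_er_bipartite(nb, nr, p, rng)
        g = sample_er_graph(nn, p, rng)
        if attr_source is not None:
            for v, attrs in zip(g.nodes, attr_source[:nn]):
                g.nodes[v].update(attrs)
        return g

    for _ in range(config.n_sims):
        draw = _draw()  # one shared draw per simulation for all metrics
        for name, fn in metrics.items():
            value = None
            g = draw
            for _attempt in range(max_resample):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        value = float(fn(g))
                    break
                except ValueError:
                    resampled[name] += 1  # incomputable on this draw: resample
                    g = _draw()
            if value is None:
                raise RuntimeError(
                    f"metric {name!r} incomputable on {max_resample} consecutive null draws"
                )
            nulls[name].append(value)

    results = []
    for name in metrics:
        arr = np.asarray(nulls[name])
        direction, pval = monte_carlo_test(observed[name], arr, two_tailed=two_tailed)
        results.append(
            NullTestResult(
                metric_name=name,
                observed=observed[name],
                null_values=arr,
                direction=direction,
                p_value=pval,
                n_resampled=resampled[name],
                meta={
                    "link_prob": p,
                    "n_sims": config.n_sims,
                    "two_tailed": two_tailed,
                    "tie_rule": "ties counted as exceedances; add-one estimator",
                },
            )
        )
    return results
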