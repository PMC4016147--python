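"""Static plot exports: network maps and removal curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx

from .removal import RemovalCurve


def plot_removal_curves(curves: dict[str, RemovalCurve], path) -> None:
    """Mean +/- SE component count vs. proportion of roosts removed."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.errorbar(
            c.proportions, c.mean_components, yerr=c.se_components, label=label,
            capsize=2, marker="o", markersize=3,
        )
    ax.set_xlabel("proportion of roosts removed")
    ax.set_ylabel("mean number of components")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_network(graph: nx.Graph, path, color_attr: str | None = None) -> None:
    """Spring-layout network map; nodes optionally coloured by an attribute."""
    fig, ax = plt.subplots(figsize=(5, 5))
    pos = nx.spring_layout(graph, seed=7)
    colors = None
    if color_attr is not None:
        levels = sorted({str(graph.nodes[n].get(color_attr)) for n in graph.nodes})
        cmap = {lv: i for i, lv in enumerate(levels)}
        colors = [cmap[str(graph.nodes[n].get(color_attr))] for n in graph.nodes]
    nx.draw_networkx(
        graph, pos=pos, ax=ax, node_size=60, with_labels=False,
        node_color=colors if colors is not None else "#347",
        cmap=plt.cm.viridis, edge_color="#999",
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
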