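"""Basic trait-network plotting.

One figure style: nodes colored by parent trait, sized by standardized
degree, optional dashed ellipses around detected modules. Layout is a
seeded spring layout so repeated plots of the same network agree.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .metrics import node_degrees

__all__ = ["plot_network"]


def plot_network(G: nx.Graph, partition=None, ax=None, layout_seed: int = 0,
                 title: str | None = None):
    """Draw a trait network; returns the matplotlib Axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    if G.number_of_nodes() == 0:
        ax.set_axis_off()
        return ax

    pos = nx.spring_layout(G, seed=layout_seed)
    traits = sorted({d.get("trait", "") for _, d in G.nodes(data=True)})
    cmap = plt.get_cmap("tab10")
    color_of = {t: cmap(i % 10) for i, t in enumerate(traits)}
    _, standardized, _ = node_degrees(G)
    sizes = [200 + 1200 * standardized[n] for n in G.nodes()]
    colors = [color_of[G.nodes[n].get("trait", "")] for n in G.nodes()]

    nx.draw_networkx_edges(G, pos, ax=ax, edge_color="black", alpha=0.6)
    nx.draw_networkx_nodes(G, pos, ax=ax, node_size=sizes, node_color=colors,
                           edgecolors="grey")
    nx.draw_networkx_labels(G, pos, ax=ax, font_size=6)

    if partition:
        for module in partition:
            pts = np.array([pos[n] for n in module if n in pos])
            if len(pts) < 2:
                continue
            center = pts.mean(axis=0)
            radii = np.abs(pts - center).max(axis=0) + 0.08
            ellipse = matplotlib.patches.Ellipse(
                center, 2 * radii[0], 2 * radii[1],
                fill=False, linestyle="--", edgecolor="grey",
            )
            ax.add_patch(ellipse)

    handles = [plt.Line2D([], [], marker="o", linestyle="", color=color_of[t], label=t)
               for t in traits if t]
    if handles:
        ax.legend(handles=handles, fontsize=7, loc="best")
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    return ax
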