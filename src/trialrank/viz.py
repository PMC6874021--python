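"""Network visualization: size, color, transparency, and position channels.

Visual encoding of the evidence network:

* node color — divergent scale over vertex value, symmetric about zero
  (negative pole red, positive pole blue, white midpoint), so that
  recommendable and contraindicated regimens pop out at a glance;
* node area — proportional to vertex size (total patients studied), area
  rather than radius to avoid perceptual exaggeration;
* node transparency — opacity decreases with the age of the vertex's
  newest incident evidence, so regimens with only outdated trials fade;
* edge color — categorical by the selected endpoint's surrogacy class
  (weak surrogates blue), making endpoint-quality drift visible;
* edge width — proportional to the contribution magnitude;
* position — deterministic force-directed layout given a seed.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # render headless; never requires a display

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
from dataclasses import dataclass, field
from matplotlib import cm, colors
from matplotlib.lines import Line2D

from .trials import SurrogacyClass
from .valuation import NetworkState

__all__ = [
    "VisualStyle",
    "assign_visual_channels",
    "layout_network",
    "render",
    "export_graphml",
]

_EDGE_CLASS_COLORS = {
    SurrogacyClass.STRONG: "#555555",
    SurrogacyClass.INTERMEDIATE: "#ff7f0e",
    SurrogacyClass.WEAK: "#1f77b4",  # weak surrogate endpoints draw blue edges
}


@dataclass(frozen=True)
class VisualStyle:
    """Resolved visual-channel parameters."""

    cmap: str = "RdBu"  # red = negative pole, blue = positive pole, white mid
    max_node_area: float = 2000.0  # matplotlib scatter points^2 for largest node
    min_node_area: float = 50.0
    max_edge_width: float = 5.0
    min_edge_width: float = 0.5
    min_alpha: float = 0.25
    alpha_age_span_half_lives: float = 3.0
    half_life_years: float = 10.0
    edge_class_colors: dict = field(
        default_factory=lambda: dict(_EDGE_CLASS_COLORS)
    )


def _node_alpha(age: float, style: VisualStyle) -> float:
    """Linear fade from 1.0 at age 0 to min_alpha at >= 3 half-lives."""
    span = style.alpha_age_span_half_lives * style.half_life_years
    frac = min(max(age / span, 0.0), 1.0)
    return 1.0 - (1.0 - style.min_alpha) * frac


def assign_visual_channels(
    state: NetworkState, style: VisualStyle | None = None
) -> nx.MultiGraph:
    """Build a styled multigraph with resolved color/area/alpha/width attributes.

    The color scale is symmetric about 0 with extremes at +-max|value|, so
    a zero-valued vertex maps exactly to the scale midpoint and +x / -x map
    to colors equidistant from it.
    """
    if style is None:
        style = VisualStyle()
    values = state.values
    vmax = max((abs(v) for v in values.values()), default=0.0) or 1.0
    norm = colors.Normalize(vmin=-vmax, vmax=vmax)
    cmap = matplotlib.colormaps[style.cmap]

    max_size = max(state.sizes.values(), default=1)
    max_mag = max((abs(e.magnitude) for e in state.edges), default=0.0) or 1.0

    min_age: dict[str, float] = {}
    for e in state.edges:
        for r in (e.regimen_a, e.regimen_b):
            min_age[r] = min(min_age.get(r, float("inf")), e.effective_age)

    g = nx.MultiGraph(eval_year=state.eval_year)
    for r in state.regimens:
        v = values[r]
        g.add_node(
            r,
            value=float(v),
            size=int(state.sizes[r]),
            color=colors.to_hex(cmap(norm(v))),
            color_pos=float(norm(v)),  # position on the divergent scale; 0.5 = neutral
            area=style.min_node_area
            + (style.max_node_area - style.min_node_area) * state.sizes[r] / max_size,
            alpha=_node_alpha(min_age.get(r, 0.0), style),
        )
    for e in state.edges:
        g.add_edge(
            e.regimen_a,
            e.regimen_b,
            trial_id=e.trial_id,
            year=e.year,
            endpoint_class=e.endpoint_class.name,
            contribution=float(e.magnitude if e.winner == e.regimen_a else -e.magnitude)
            if e.winner is not None
            else 0.0,
            color=style.edge_class_colors[e.endpoint_class],
            width=style.min_edge_width
            + (style.max_edge_width - style.min_edge_width)
            * abs(e.magnitude)
            / max_mag,
        )
    return g


def layout_network(graph: nx.Graph, seed: int = 0) -> dict:
    """Deterministic force-directed positions; a lone vertex sits at the origin."""
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): np.zeros(2)}
    return nx.spring_layout(graph, seed=seed)


def render(
    graph: nx.Graph,
    positions: dict,
    path: str | Path,
    fmt: str | None = None,
    title: str | None = None,
) -> Path:
    """Draw the styled, positioned network to SVG or PNG with a legend.

    The legend carries the value color bar, a node-size key, the
    edge-class key, and the evaluation-year stamp.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "svg"
    fmt = fmt.lower()
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported format {fmt!r}; expected 'svg' or 'png'")

    fig, ax = plt.subplots(figsize=(9, 7))
    node_values = [graph.nodes[n]["value"] for n in graph.nodes]
    vmax = max((abs(v) for v in node_values), default=0.0) or 1.0

    for u, v, data in graph.edges(data=True):
        x = [positions[u][0], positions[v][0]]
        y = [positions[u][1], positions[v][1]]
        ax.plot(x, y, color=data["color"], linewidth=data["width"], zorder=1, alpha=0.8)

    for n in graph.nodes:
        d = graph.nodes[n]
        ax.scatter(
            positions[n][0],
            positions[n][1],
            s=d["area"],
            c=d["color"],
            alpha=d["alpha"],
            edgecolors="black",
            linewidths=0.5,
            zorder=2,
        )
        ax.annotate(
            n,
            positions[n],
            fontsize=7,
            ha="center",
            va="center",
            zorder=3,
        )

    sm = cm.ScalarMappable(
        norm=colors.Normalize(vmin=-vmax, vmax=vmax), cmap=plt.get_cmap("RdBu")
    )
    cbar = fig.colorbar(sm, ax=ax, shrink=0.7)
    cbar.set_label("vertex value")

    legend_items = [
        Line2D([], [], color=c, linewidth=2, label=f"{cls.name.lower()} endpoint")
        for cls, c in _EDGE_CLASS_COLORS.items()
    ]
    legend_items.append(
        Line2D(
            [], [], marker="o", color="none", markerfacecolor="gray",
            markersize=10, label="node area ∝ patients studied",
        )
    )
    ax.legend(handles=legend_items, loc="lower left", fontsize=7)

    eval_year = graph.graph.get("eval_year", "")
    ax.set_title(title or f"Treatment regimen network — {eval_year}")
    ax.text(
        0.99, 0.01, f"evaluated at year {eval_year}",
        transform=ax.transAxes, ha="right", fontsize=8,
    )
    ax.set_axis_off()
    fig.savefig(path, format=fmt, bbox_inches="tight")
    plt.close(fig)
    return path


def export_graphml(state: NetworkState, path: str | Path, epsilon: float = 0.5) -> Path:
    """Write the network to GraphML with typed node and edge attributes.

    Nodes carry value (double), size (long) and interpretation (string);
    edges carry trial_id, year, endpoint class and the signed contribution
    oriented from the first endpoint.  The file round-trips through any
    generic GraphML reader.
    """
    from .analysis import _interpret

    path = Path(path)
    g = nx.MultiGraph()
    values = state.values
    for r in state.regimens:
        g.add_node(
            r,
            value=float(values[r]),
            size=int(state.sizes[r]),
            interpretation=_interpret(values[r], epsilon),
        )
    for e in state.edges:
        g.add_edge(
            e.regimen_a,
            e.regimen_b,
            trial_id=e.trial_id,
            year=int(e.year),
            endpoint_class=e.endpoint_class.name,
            contribution=float(
                e.magnitude if e.winner == e.regimen_a else -e.magnitude
            )
            if e.winner is not None
            else 0.0,
        )
    nx.write_graphml(g, path)
    return path
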