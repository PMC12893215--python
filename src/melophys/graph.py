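"""Change-point connectivity graphs.

Concentric-ring rendering of supra-threshold canonical loadings: one
ring per retained variate (outermost = variate 1), musical variables on
the left half, physiological on the right, circle size ~ |loading|,
red positive / blue negative, and edges between every surviving
music-physiology pair whose sign is the product of the loading signs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

DISPLAY_THRESHOLD = 0.3


@dataclass
class ConnectivityGraph:
    threshold: float
    variates: list = field(default_factory=list)  # one nx.Graph per retained variate

    def to_dict(self) -> dict:
        out = {"threshold": self.threshold, "variates": []}
        for g in self.variates:
            out["variates"].append({
                "variate": g.graph["variate"],
                "nodes": [
                    dict(name=n, side=d["side"], loading=d["loading"])
                    for n, d in sorted(g.nodes(data=True))
                ],
                "edges": [
                    dict(music=u, physiology=v, sign=d["sign"])
                    for u, v, d in sorted(g.edges(data=True))
                ],
            })
        return out


def build_graph(x_loadings, y_loadings, retained=None, threshold: float = DISPLAY_THRESHOLD) -> ConnectivityGraph:
    """Filter loadings by |value| > threshold (strict) and connect pairs.

    ``x_loadings``/``y_loadings`` are the labelled loading tables from
    :func:`melophys.cca.loadings`; ``retained`` selects variates (all by
    default). Annotation-category nodes carry no intrinsic direction;
    the edge sign defers to the physiological loading sign.
    """
    k = x_loadings.shape[1]
    if retained is None:
        retained = np.ones(k, dtype=bool)
    graphs = []
    any_node = False
    for i in range(k):
        if not retained[i]:
            continue
        g = nx.Graph(variate=i + 1)
        music = [(v, x_loadings.iloc[:, i][v]) for v in x_loadings.index
                 if abs(x_loadings.iloc[:, i][v]) > threshold]
        physio = [(v, y_loadings.iloc[:, i][v]) for v in y_loadings.index
                  if abs(y_loadings.iloc[:, i][v]) > threshold]
        for v, ld in music:
            g.add_node(v, side="music", loading=float(ld))
        for v, ld in physio:
            g.add_node(v, side="physiology", loading=float(ld))
        for mv, ml in music:
            for pv, pl in physio:
                g.add_edge(mv, pv, sign=int(np.sign(ml) * np.sign(pl)))
        any_node = any_node or g.number_of_nodes() > 0
        graphs.append(g)
    if graphs and not any_node:
        warnings.warn(f"no loading exceeds the display threshold {threshold}", stacklevel=2)
    return ConnectivityGraph(threshold=threshold, variates=graphs)


def save_graph(graph: ConnectivityGraph, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(graph.to_dict(), indent=1))


def render(graph: ConnectivityGraph, path, dpi: int = 150) -> None:
    """Write the concentric-ring figure (SVG or PNG by file extension).

    Output bytes are deterministic for a fixed graph and settings.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with plt.rc_context({"svg.hashsalt": "melophys"}):
        fig, ax = plt.subplots(figsize=(7, 7))
        ax.set_aspect("equal")
        ax.axis("off")
        n_rings = max(len(graph.variates), 1)
        captions = []
        for ring_idx, g in enumerate(graph.variates):
            radius = 1.0 - ring_idx * (0.8 / n_rings)  # outermost = variate 1
            circ = plt.Circle((0, 0), radius, fill=False, color="black", lw=1)
            ax.add_patch(circ)
            music = sorted(n for n, d in g.nodes(data=True) if d["side"] == "music")
            physio = sorted(n for n, d in g.nodes(data=True) if d["side"] == "physiology")
            pos = {}
            for names, (a0, a1) in ((music, (100, 260)), (physio, (-80, 80))):
                angles = np.linspace(a0, a1, len(names) + 2)[1:-1] if names else []
                for name, ang in zip(names, angles):
                    rad = np.deg2rad(ang)
                    pos[name] = (radius * np.cos(rad), radius * np.sin(rad))
            for u, v, d in sorted(g.edges(data=True)):
                style = "-" if d["sign"] > 0 else "--"
                ax.plot(*zip(pos[u], pos[v]), style, color="grey", lw=0.8, zorder=1)
            for name, d in sorted(g.nodes(data=True)):
                x, y = pos[name]
                color = "red" if d["loading"] > 0 else "blue"
                ax.scatter([x], [y], s=600 * abs(d["loading"]), c=color, zorder=2)
                ax.annotate(name, (x, y), textcoords="offset points",
                            xytext=(0, 10), ha="center", fontsize=7)
            if g.number_of_nodes():
                top = max(g.nodes(data=True), key=lambda nd: abs(nd[1]["loading"]))
                captions.append(
                    f"variate {g.graph['variate']}: dominant {top[0]} "
                    f"({top[1]['loading']:+.2f})"
                )
        caption = "; ".join(captions) if captions else "no supra-threshold loadings"
        ax.set_title(f"change-point connectivity (|loading| > {graph.threshold})", fontsize=10)
        ax.text(0, -1.25, caption, ha="center", fontsize=8)
        ax.set_xlim(-1.3, 1.3)
        ax.set_ylim(-1.35, 1.3)
        fig.savefig(path, dpi=dpi, metadata=_deterministic_metadata(str(path)))
        plt.close(fig)


def _deterministic_metadata(path: str) -> dict:
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return {}
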