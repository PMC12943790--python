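"""Triangular-diagram rendering with matplotlib.

Follows the visual conventions of melt-diagram figures in the resolution
literature: circled phase markers at their stoichiometric positions, colored
dominating-phase domains, eutectic points, the 1:1 test composition as a red
cross, and (when available) the recommended racemate:agent mixing-ratio
segment as a dotted line.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .phases import TEST_COMPOSITION
from .ternary import DomainMap, TernaryDiagram, simplex_to_xy

__all__ = ["plot_ternary"]


def plot_ternary(
    diagram: TernaryDiagram,
    domain_map: Optional[DomainMap] = None,
    grid_density: int = 121,
    show_test_point: bool = True,
    mixing_segment: Optional[tuple[float, float]] = None,
    ax=None,
):
    """Render a ternary diagram; returns the matplotlib figure."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 6.5))
    else:
        fig = ax.figure
    if domain_map is None:
        domain_map = diagram.domain_map(grid_density)

    names = sorted({l for l in domain_map.labels if l is not None})
    cmap = plt.get_cmap("tab10")
    color_of = {n: cmap(i % 10) for i, n in enumerate(names)}

    xs, ys, cs = [], [], []
    for c, l in zip(domain_map.points, domain_map.labels):
        if l is None:
            continue
        x, y = simplex_to_xy(c)
        xs.append(x)
        ys.append(y)
        cs.append(color_of[l])
    ax.scatter(xs, ys, c=cs, s=6, marker="h", linewidths=0, alpha=0.6, zorder=1)

    corners = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 0, 0)]
    cx, cy = zip(*(simplex_to_xy(c) for c in corners))
    ax.plot(cx, cy, color="black", lw=1.2, zorder=3)

    for sub in diagram.subternaries:
        pts = [simplex_to_xy(p.coords) for p in sub.phases] + [
            simplex_to_xy(sub.phases[0].coords)
        ]
        px, py = zip(*pts)
        ax.plot(px, py, color="gray", lw=0.5, ls="--", zorder=2)

    for p in diagram.phases:
        x, y = simplex_to_xy(p.coords)
        ax.plot(x, y, "o", mfc="white", mec="black", ms=11, zorder=4)
        ax.annotate(
            p.name, (x, y), textcoords="offset points", xytext=(0, 11),
            ha="center", fontsize=9, zorder=5,
        )

    for names_key, (comp, t_eu, _) in diagram.eutectics.items():
        x, y = simplex_to_xy(comp.fractions)
        ax.plot(x, y, "*", color="black", ms=8, zorder=4)
        ax.annotate(
            f"{t_eu - 273.15:.0f}°C", (x, y), textcoords="offset points",
            xytext=(0, -12), ha="center", fontsize=7, zorder=5,
        )

    if mixing_segment is not None:
        t = np.linspace(mixing_segment[0], mixing_segment[1], 50)
        seg = [((1 - v) / 2, (1 - v) / 2, v) for v in t]
        sx, sy = zip(*(simplex_to_xy(c) for c in seg))
        ax.plot(sx, sy, color="purple", ls=":", lw=2.0, zorder=4,
                label="recommended mixing ratios")
        ax.legend(loc="upper right", fontsize=8)

    if show_test_point:
        x, y = simplex_to_xy(TEST_COMPOSITION.fractions)
        ax.plot(x, y, "+", color="red", ms=14, mew=2.5, zorder=6)

    labels = diagram.base_components
    ax.annotate(labels[0], simplex_to_xy((1, 0, 0)), xytext=(-5, -14),
                textcoords="offset points", ha="center", fontsize=10)
    ax.annotate(labels[1], simplex_to_xy((0, 1, 0)), xytext=(5, -14),
                textcoords="offset points", ha="center", fontsize=10)
    ax.annotate(labels[2], simplex_to_xy((0, 0, 1)), xytext=(0, 10),
                textcoords="offset points", ha="center", fontsize=10)

    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_xlim(-0.12, 1.12)
    ax.set_ylim(-0.12, 1.0)
    return fig
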