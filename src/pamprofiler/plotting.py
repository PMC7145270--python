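"""Matplotlib views of PAM statistics: an information-scaled logo-style
stack and the hierarchical PAM wheel (sunburst)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .reporter_pam import PamProfile, PamWheelNode

BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_logo(profile: PamProfile, ic: np.ndarray):
    """Information-scaled stacked-bar logo: per position, bars of height
    f[b] * IC stacked smallest-first (the sequence-logo layout, drawn with
    bars rather than glyphs)."""
    fig, ax = plt.subplots(figsize=(1.2 * profile.k + 1, 3))
    for x, (pos, row) in enumerate(profile.frequencies.iterrows(), start=1):
        bottom = 0.0
        for base, freq in sorted(row.items(), key=lambda kv: kv[1]):
            height = freq * ic[x - 1]
            ax.bar(x, height, bottom=bottom, color=BASE_COLORS[base], width=0.8,
                   label=base if x == 1 else None)
            if height > 0.15:
                ax.text(x, bottom + height / 2, base, ha="center", va="center",
                        fontsize=9, fontweight="bold", color="white")
            bottom += height
    ax.set_xticks(range(1, profile.k + 1))
    ax.set_xlabel("PAM position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    fig.tight_layout()
    return fig


def plot_pam_wheel(root: PamWheelNode):
    """Sunburst of the PAM tally: ring j partitions by the base at position
    j, arc width proportional to joint frequency."""
    import matplotlib.patches as mpatches

    fig, ax = plt.subplots(figsize=(5, 5), subplot_kw={"aspect": "equal"})
    total = root.count

    def draw_ring(node: PamWheelNode, theta0: float) -> None:
        theta = theta0
        for base in sorted(node.children):
            child = node.children[base]
            width = 360.0 * child.count / total
            ax.add_patch(
                mpatches.Wedge(
                    (0, 0), 0.35 * (child.depth + 1), theta, theta + width,
                    width=0.35, facecolor=BASE_COLORS[base], edgecolor="white", linewidth=0.3,
                )
            )
            if width > 12:
                mid = np.deg2rad(theta + width / 2)
                r = 0.35 * (child.depth + 1) - 0.17
                ax.text(r * np.cos(mid), r * np.sin(mid), base, ha="center", va="center", fontsize=8)
            draw_ring(child, theta)
            theta += width

    draw_ring(root, 0.0)
    depth = _max_depth(root)
    lim = 0.35 * (depth + 1) + 0.1
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axis("off")
    fig.tight_layout()
    return fig


def _max_depth(node: PamWheelNode) -> int:
    if not node.children:
        return node.depth
    return max(_max_depth(c) for c in node.children.values())
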