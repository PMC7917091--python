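"""Static plots: Ks distribution with fitted modes, and a synteny dot plot."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_ks_distribution", "plot_dotplot"]


def plot_ks_distribution(ks_values: Sequence[float], modes: Sequence[float] = (),
                         path: str = "ks_distribution.png", bins: int = 60,
                         ks_max: float = 2.0) -> None:
    ks = np.asarray([k for k in ks_values if k is not None and 0 < k <= ks_max])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(ks, bins=bins, color="#7c6bb5", alpha=0.75, density=True)
    for m in modes:
        ax.axvline(m, color="crimson", linestyle="--", lw=1)
        ax.annotate(f"Ks={m:.2f}", (m, ax.get_ylim()[1] * 0.9), fontsize=8,
                    rotation=90, ha="right")
    ax.set_xlabel("Ks (synonymous substitutions per synonymous site)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dotplot(blocks: Iterable, path: str = "dotplot.png") -> None:
    """Anchor dot plot; one colour per syntenic block."""
    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("tab20")
    for i, b in enumerate(blocks):
        xs = [a.rank_a for a in b.anchors]
        ys = [a.rank_b for a in b.anchors]
        ax.plot(xs, ys, ".", ms=3, color=cmap(i % 20))
    ax.set_xlabel("gene rank (genome A)")
    ax.set_ylabel("gene rank (genome B)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
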