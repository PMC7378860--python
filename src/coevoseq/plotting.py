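"""Plot the 2D genotype map with lineage edges.

One scatter per figure: points are genotypes (coloured by RNA class, sized
by frequency), solid lines join within-class pairs one Hamming distance
apart, dashed lines join cross-class perfect matches (deletion ignored).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

import numpy as np  # noqa: E402

from .calling import Genotype  # noqa: E402
from .space import EdgeSet  # noqa: E402

_CLASS_COLOURS = {
    "host": "#1f5fbf",
    "parasite-alpha": "#c23b3b",
    "parasite-beta": "#2e8b57",
    "parasite-gamma": "#7d3fbf",
}


def plot_genotype_map(
    genotypes: Sequence[Genotype],
    coordinates: np.ndarray,
    edges: EdgeSet,
    path: str | Path,
    rounds: Sequence[int] | None = None,
    title: str | None = None,
) -> None:
    """Write a genotype-map snapshot (optionally restricted to rounds)."""
    keep = [
        i for i, g in enumerate(genotypes)
        if rounds is None or g.round in rounds
    ]
    keep_set = set(keep)
    fig, ax = plt.subplots(figsize=(6, 5))
    for pairs, style in ((edges.within, "-"), (edges.cross, "--")):
        for i, j in pairs:
            if i in keep_set and j in keep_set:
                ax.plot(
                    coordinates[[i, j], 0], coordinates[[i, j], 1],
                    style, color="black", linewidth=0.6, zorder=1,
                )
    for i in keep:
        g = genotypes[i]
        ax.scatter(
            coordinates[i, 0], coordinates[i, 1],
            s=10 + 120 * g.frequency,
            color=_CLASS_COLOURS.get(g.class_label, "grey"),
            edgecolors="none", alpha=0.8, zorder=2,
        )
    ax.set_xlabel("PCo 1")
    ax.set_ylabel("PCo 2")
    if title:
        ax.set_title(title)
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
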