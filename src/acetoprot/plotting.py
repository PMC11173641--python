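"""Figure helpers: stacked taxon-frequency bars and clustered heat maps.

Rendering is optional sugar over the tidy TSV outputs; nothing downstream
depends on it. Uses the non-interactive Agg backend so it works headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diffquant import Dendrogram
from .profiling import TaxonProfile

__all__ = ["plot_taxon_bars", "plot_heatmap"]


def plot_taxon_bars(profiles: list[TaxonProfile], path: str | Path,
                    main_threshold: float = 1.0) -> None:
    """Stacked bars of main-taxon frequencies per scope group; minor taxa
    are pooled into an 'other (<threshold)' band."""
    scopes = [p.scope_label for p in profiles]
    main = sorted({t for p in profiles for t, _, _ in p.main_taxa(main_threshold)})
    fig, ax = plt.subplots(figsize=(1.5 + len(scopes), 4))
    bottom = np.zeros(len(scopes))
    for taxon in main:
        freqs = np.array([p.frequency(taxon) for p in profiles])
        ax.bar(scopes, freqs, bottom=bottom, label=taxon)
        bottom += freqs
    ax.bar(scopes, 100.0 - bottom, bottom=bottom,
           label=f"other (<{main_threshold:g}%)", color="lightgrey")
    ax.set_ylabel("frequency (% of proteins)")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(zscores: pd.DataFrame, dendrogram: Dendrogram,
                 path: str | Path) -> None:
    """Heat map of row-z-scored group means in dendrogram leaf order."""
    order = dendrogram.leaf_order()
    data = zscores.loc[order]
    fig, ax = plt.subplots(figsize=(2 + 0.6 * data.shape[1],
                                    max(3.0, 0.08 * data.shape[0])))
    image = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r",
                      vmin=-2, vmax=2, interpolation="nearest")
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=45, ha="right")
    ax.set_yticks([])
    ax.set_xlabel("sampling time")
    fig.colorbar(image, ax=ax, label="z-score of mean abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
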