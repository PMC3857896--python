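"""Selection-frequency tables and expression heatmaps.

Because the external B.632+ protocol runs the selector on B bootstrap
sets plus the original data, it produces B + 1 DEG sets (201 with the
default B = 200).  The frequency with which each gene enters those sets
is a stability measure; the heatmap shows the top genes' normalized
expression across samples, with a class color bar, ordered by frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset


@dataclass
class FrequencyTable:
    """Per-gene appearance counts across a collection of DEG sets."""

    counts: dict[int, int]
    n_sets: int

    def top(self, k: int) -> list[int]:
        """Gene indices by descending count; ties go to the lower index."""
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [gene for gene, _ in ranked[:k]]

    def to_frame(self) -> pd.DataFrame:
        order = self.top(len(self.counts))
        return pd.DataFrame(
            {"gene_index": order, "count": [self.counts[g] for g in order]}
        )


def deg_frequency(deg_sets) -> FrequencyTable:
    """Count how often each gene appears across the given gene-index sets."""
    deg_sets = list(deg_sets)
    if not deg_sets:
        raise ValueError("need at least one DEG set")
    counter: Counter[int] = Counter()
    for genes in deg_sets:
        counter.update(set(int(g) for g in genes))
    return FrequencyTable(counts=dict(counter), n_sets=len(deg_sets))


def render_heatmap(
    ds: ExpressionDataset,
    genes,
    out,
    sidecar_csv=None,
    title: str | None = None,
):
    """Draw a genes × samples heatmap with a class color bar on top.

    Rows are the given genes in the given (frequency) order; values are
    per-gene z-scores for display only.  A sidecar CSV echoes the plotted
    matrix row-for-row.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = [int(g) for g in genes]
    if any(g >= ds.n_genes for g in genes):
        raise ValueError("gene index outside dataset")
    block = ds.values[:, genes].T  # genes × samples
    mu = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    display = (block - mu) / sd

    fig, (ax_bar, ax_map) = plt.subplots(
        2,
        1,
        figsize=(max(4, ds.n_samples * 0.25), max(3, len(genes) * 0.25)),
        gridspec_kw={"height_ratios": [1, 20]},
        constrained_layout=True,
    )
    ax_bar.imshow(
        (ds.labels == 1)[None, :], aspect="auto", cmap="coolwarm", vmin=0, vmax=1
    )
    ax_bar.set_yticks([])
    ax_bar.set_xticks([])
    ax_bar.set_title(title or "class (+1 red / -1 blue)", fontsize=8)
    im = ax_map.imshow(display, aspect="auto", cmap="RdBu_r")
    ax_map.set_xlabel("samples")
    ax_map.set_ylabel("genes (descending selection frequency)")
    ax_map.set_yticks(range(len(genes)))
    ax_map.set_yticklabels([ds.gene_ids[g] for g in genes], fontsize=6)
    fig.colorbar(im, ax=ax_map, shrink=0.6, label="z-scored expression")
    fig.savefig(out, dpi=120)
    plt.close(fig)

    if sidecar_csv is not None:
        pd.DataFrame(
            display,
            index=[ds.gene_ids[g] for g in genes],
            columns=ds.sample_ids,
        ).to_csv(sidecar_csv)
    return out
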