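"""Optional heatmap and average-profile plotting helpers.

The tested artifacts are the sorted matrices themselves; these helpers
render them in the conventional style (yellow = nucleosomal signal /
MNase-sensitive, blue = MNase-resistant).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .containers import PromoterMatrix
from .matrix_ops import SortOrder, apply_sort


def occupancy_heatmap(
    matrix: PromoterMatrix,
    path: str | Path,
    order: SortOrder | None = None,
    vmax_quantile: float = 0.98,
) -> None:
    if order is not None:
        matrix = apply_sort(matrix, order)
    vals = matrix.values.to_numpy(dtype=float)
    vmax = np.nanquantile(vals, vmax_quantile)
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(
        vals, aspect="auto", cmap="cividis", vmin=0, vmax=vmax,
        extent=[matrix.window_centers[0], matrix.window_centers[-1],
                len(matrix.gene_ids), 0],
    )
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("promoters")
    ax.set_title(matrix.metadata.get("label", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sensitivity_heatmap(
    matrix: PromoterMatrix,
    path: str | Path,
    order: SortOrder | None = None,
    limit: float = 2.0,
) -> None:
    """Diverging blue (MRF) to yellow (MSF) heatmap of log2(light/heavy)."""
    if order is not None:
        matrix = apply_sort(matrix, order)
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(
        matrix.values.to_numpy(dtype=float), aspect="auto", cmap="cividis",
        vmin=-limit, vmax=limit,
        extent=[matrix.window_centers[0], matrix.window_centers[-1],
                len(matrix.gene_ids), 0],
    )
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("promoters")
    ax.set_title(matrix.metadata.get("label", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def average_profiles(
    profiles: pd.DataFrame,
    path: str | Path,
    ylabel: str = "mean signal",
) -> None:
    """One line per group (cluster or quartile) across the promoter span."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.asarray(profiles.columns, dtype=float)
    for label, row in profiles.iterrows():
        ax.plot(x, row.to_numpy(dtype=float), label=str(label), lw=1.2)
    ax.axvline(0, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
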