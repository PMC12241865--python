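"""Report emission: presence/window heatmap tables and optional PNG plots.

The presence heatmap mirrors the red/yellow sample-by-locus grids used to
display cohort calls (red = positive, yellow = negative); the window-count
heatmap shows ``n_usable_windows`` per cell on the same layout.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap

from .cohort import PresenceMatrix

logger = logging.getLogger(__name__)


def heatmap_table(matrix: PresenceMatrix, region_ids: list[str] | None = None) -> pd.DataFrame:
    """Long-format heatmap table; empty (header-only) when no regions remain."""
    if region_ids is not None:
        if not region_ids:
            logger.warning("empty region set: emitting header-only heatmap table")
            return pd.DataFrame(
                columns=[
                    "sample_id", "cohort", "region_id", "status",
                    "n_usable_windows", "locus_depth",
                ]
            )
        matrix = matrix.subset_regions(region_ids)
    return matrix.to_long_frame()


def plot_presence_heatmap(
    matrix: PresenceMatrix,
    path: str | Path,
    region_ids: list[str] | None = None,
) -> None:
    """Red (positive) / yellow (negative) presence grid as PNG."""
    if region_ids:
        matrix = matrix.subset_regions(region_ids)
    data = matrix.status.astype(int)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.18 * data.shape[1]), max(3, 0.18 * data.shape[0]))
    )
    ax.imshow(data.to_numpy(), cmap=ListedColormap(["gold", "firebrick"]),
              vmin=0, vmax=1, aspect="auto", interpolation="nearest")
    ax.set_xticks(np.arange(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=4)
    ax.set_yticks(np.arange(data.shape[0]))
    ax.set_yticklabels(data.index, fontsize=4)
    ax.set_xlabel("locus")
    ax.set_ylabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=200)
    plt.close(fig)


def plot_window_heatmap(
    matrix: PresenceMatrix,
    path: str | Path,
    region_ids: list[str] | None = None,
) -> None:
    """Usable-window-count grid (samples x loci) as PNG."""
    if region_ids:
        matrix = matrix.subset_regions(region_ids)
    data = matrix.windows
    fig, ax = plt.subplots(
        figsize=(max(4, 0.18 * data.shape[1]), max(3, 0.18 * data.shape[0]))
    )
    im = ax.imshow(data.to_numpy(), cmap="viridis", aspect="auto",
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label="usable windows")
    ax.set_xticks(np.arange(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=4)
    ax.set_yticks(np.arange(data.shape[0]))
    ax.set_yticklabels(data.index, fontsize=4)
    fig.tight_layout()
    fig.savefig(path, dpi=200)
    plt.close(fig)


def run_summary(matrix: PresenceMatrix) -> pd.DataFrame:
    """Per-cohort counts of samples and positive calls."""
    rows = []
    for cohort in matrix.cohorts.unique():
        ids = matrix.samples_in_cohort(cohort)
        sub = matrix.status.loc[ids]
        rows.append(
            {
                "cohort": cohort,
                "n_samples": len(ids),
                "n_positive_calls": int(sub.to_numpy().sum()),
                "n_regions_ever_positive": int(sub.any(axis=0).sum()),
            }
        )
    return pd.DataFrame(rows)
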