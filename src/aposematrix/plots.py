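"""Report figures: discriminant scatter and contrast boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .uniqueness import FeatureMatrix


def discriminant_scatter(fm: FeatureMatrix, path: str | Path) -> None:
    """Specimens projected on the first two discriminant axes, one
    colour per class."""
    lda = LinearDiscriminantAnalysis(n_components=2).fit(fm.x, fm.labels)
    z = lda.transform(fm.x)
    fig, ax = plt.subplots(figsize=(7, 6))
    for c in np.unique(fm.labels):
        sel = fm.labels == c
        ax.scatter(z[sel, 0], z[sel, 1], s=12, label=str(c), alpha=0.7)
    ax.set_xlabel("discriminant axis 1")
    ax.set_ylabel("discriminant axis 2")
    ax.legend(fontsize=6, ncol=2, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def contrast_boxplot(table: pd.DataFrame, path: str | Path,
                     response: str = "log_chromatic") -> None:
    """Contrast by background type, split by habitat use."""
    df = table.dropna(subset=[response])
    habitats = sorted(df["habitat_use"].unique())
    fig, axes = plt.subplots(1, len(habitats), figsize=(4 * len(habitats), 4),
                             sharey=True, squeeze=False)
    for ax, hab in zip(axes[0], habitats):
        sub = df[df["habitat_use"] == hab]
        groups = [sub.loc[sub["bg_type"] == t, response] for t in ("own", "green", "brown")]
        ax.boxplot(groups, tick_labels=["own", "green", "brown"])
        ax.set_title(hab)
        ax.set_xlabel("background")
    axes[0][0].set_ylabel(response)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
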