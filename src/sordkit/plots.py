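"""Plotting helpers for validation reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import BlandAltman, ConfusionMatrix


def bland_altman_plot(
    results: dict[str, BlandAltman],
    percent_times: dict[str, dict[str, tuple[float, float]]],
    path: str | Path,
) -> None:
    """One Bland-Altman panel per activity class (mean vs difference)."""
    classes = list(results)
    fig, axes = plt.subplots(1, len(classes), figsize=(4 * len(classes), 3.5), squeeze=False)
    for ax, cls in zip(axes[0], classes):
        ba = results[cls]
        idx = np.array([v[cls][0] for v in percent_times.values()])
        ref = np.array([v[cls][1] for v in percent_times.values()])
        means = (idx + ref) / 2.0
        ax.scatter(means, ref - idx, s=18, alpha=0.8)
        ax.axhline(ba.mean_bias, color="k", lw=1, label=f"bias {ba.mean_bias:.2f}%")
        for v in (ba.loa_low, ba.loa_high):
            ax.axhline(v, color="k", lw=1, ls="--")
        ax.axhspan(-ba.acceptability_band, ba.acceptability_band, color="green", alpha=0.07)
        ax.set_title(cls)
        ax.set_xlabel("mean of methods (% time)")
        ax.set_ylabel("reference − device (%)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def confusion_plot(cm: ConfusionMatrix, path: str | Path) -> None:
    """Heatmap of the confusion matrix (rows = predicted, columns = actual)."""
    fig, ax = plt.subplots(figsize=(1.2 * len(cm.classes) + 2, 1.2 * len(cm.classes) + 1.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center", fontsize=9)
    ax.set_xticks(range(len(cm.classes)), cm.classes, rotation=30, ha="right")
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("actual")
    ax.set_ylabel("predicted")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
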