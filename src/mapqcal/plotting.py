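"""Convenience plots over the metric tables (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .evaluate import CalibrationBin, PRPoint


def plot_precision_recall(points: Sequence[PRPoint], path: str | Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(
        [p.recall for p in points],
        [p.precision for p in points],
        c=[p.threshold for p in points],
        cmap="viridis",
        s=18,
    )
    ax.plot([p.recall for p in points], [p.precision for p in points], lw=0.8, color="grey")
    fig.colorbar(sc, ax=ax, label="threshold")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_calibration(bins: Sequence[CalibrationBin], path: str | Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nonempty = [b for b in bins if b.n > 0]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1, label="perfect calibration")
    ax.scatter(
        [b.mean_p for b in nonempty],
        [b.empirical_accuracy for b in nonempty],
        s=[max(10, min(200, b.n / 50)) for b in nonempty],
        color="tab:blue",
        label="prediction bins",
    )
    ax.set_xlabel("mean predicted p(correct)")
    ax.set_ylabel("empirical accuracy")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
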