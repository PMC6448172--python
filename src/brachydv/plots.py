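"""Figure helpers: convergence curves and delta boxplots.

Thin matplotlib wrappers over the tidy tables the pipeline emits; meant
for quick inspection, not publication styling.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_convergence", "plot_delta_boxplots"]


def plot_convergence(summary: pd.DataFrame, path: str | Path) -> None:
    """CI width vs point count, one panel per sampling series, log-log.

    ``summary`` is the output of :func:`brachydv.pipeline.convergence_study`.
    """
    series = list(summary["series"].unique())
    fig, axes = plt.subplots(1, len(series), figsize=(6 * len(series), 4.5), squeeze=False)
    for ax, ser in zip(axes[0], series):
        sub = summary[summary["series"] == ser]
        for (organ, index), grp in sub.groupby(["organ", "index"]):
            grp = grp.sort_values("amount")
            ax.plot(grp["amount"], grp["ci_width"], marker="o", label=f"{organ} {index}")
        ax.set_xscale("log", base=2)
        ax.set_yscale("log")
        ax.set_xlabel("points per ROI" if ser == "per_roi" else "points per cm³")
        ax.set_ylabel("95% CI width (%)")
        ax.set_title(ser)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_delta_boxplots(deltas: pd.DataFrame, path: str | Path) -> None:
    """Per-setting boxplots of the index deltas versus baseline.

    ``deltas`` is the output of :func:`brachydv.pipeline.run_sensitivity`;
    whiskers span the full range (0%/100%), boxes the quartiles.
    """
    indices = deltas[["organ", "index"]].drop_duplicates().itertuples(index=False)
    indices = [f"{o}:{i}" for o, i in indices]
    settings = list(deltas["setting"].unique())
    fig, axes = plt.subplots(
        len(settings), 1, figsize=(0.8 * len(indices) + 2, 2.2 * len(settings)), squeeze=False
    )
    for ax, setting in zip(axes[:, 0], settings):
        sub = deltas[deltas["setting"] == setting]
        data = [
            sub[(sub.organ == key.split(":")[0]) & (sub["index"] == key.split(":")[1])]["delta"]
            .dropna()
            .to_numpy()
            for key in indices
        ]
        ax.boxplot(data, tick_labels=indices, whis=(0, 100))
        ax.axhline(0.0, color="gray", lw=0.7)
        ax.set_ylabel("Δ vs baseline (%)")
        ax.set_title(setting, fontsize=8)
        ax.tick_params(axis="x", labelrotation=45, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
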