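"""Static figure export: per-epoch correlation panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .evaluation import MEASURES, VERB_SETS

_MEASURE_TITLES = {
    "diff": "Difference score (less - more)",
    "less": "Less-transparent form",
    "more": "More-transparent form",
}


def plot_correlation_series(series: pd.DataFrame, path, title: str | None = None) -> None:
    """Three panels (diff / less / more), seen and unseen lines with +/-1 SD bars."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharey=True)
    for ax, measure in zip(axes, MEASURES):
        for verb_set, color in zip(VERB_SETS, ("C0", "C1")):
            sub = series[(series.measure == measure) & (series.verb_set == verb_set)]
            ax.errorbar(
                sub["epoch"],
                sub["mean_r"],
                yerr=sub["sd_r"],
                label=verb_set,
                color=color,
                linewidth=1.2,
                elinewidth=0.5,
                capsize=1.5,
            )
        ax.axhline(0.0, color="grey", linewidth=0.6)
        ax.set_title(_MEASURE_TITLES[measure], fontsize=10)
        ax.set_xlabel("epoch")
    axes[0].set_ylabel("model-human Pearson r")
    axes[0].set_ylim(-1, 1)
    axes[0].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
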