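"""Optional figure rendering: importance bar charts and the predictor
correlation heat map."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_importance", "plot_correlation"]


def plot_importance(importance: pd.DataFrame, path=None, title="Permutation importance"):
    """Horizontal bar chart of mean F1 decrease per feature (sd as error
    bars when present). Returns the matplotlib figure; saves PNG if a
    path is given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = "mean_f1_decrease" if "mean_f1_decrease" in importance else "f1_decrease"
    data = importance.sort_values(col)
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(data) + 1.5))
    err = data["sd_f1_decrease"] if "sd_f1_decrease" in data else None
    ax.barh(data.index, data[col], xerr=err, color="#c44e52")
    ax.set_xlabel("decrease in F1 score")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_correlation(corr: pd.DataFrame, path=None, title="Predictor correlation"):
    """Correlation heat map with a symmetric [-1, 1] colour scale."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.5 * len(corr) + 2, 0.5 * len(corr) + 1.5))
    im = ax.imshow(corr.to_numpy(), vmin=-1.0, vmax=1.0, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
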