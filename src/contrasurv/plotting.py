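"""Optional plots: Kaplan-Meier curves and 2-D embedding maps.

Decorative output only — no numerical result depends on these. The
embedding map delegates dimensionality reduction to scikit-learn's t-SNE.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import EmbeddingMatrix, SurvivalOutcome

__all__ = ["plot_km_curves", "plot_embedding_map"]


def plot_km_curves(curves: dict[str, pd.DataFrame], path: str | Path,
                   title: str = "Risk-stratified survival") -> Path:
    """Step plot of per-group KM curves (as produced by
    ``median_split_logrank``); writes a PNG and returns its path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=group)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend(title="risk group")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_embedding_map(embeddings: EmbeddingMatrix,
                       outcomes: SurvivalOutcome, path: str | Path,
                       horizon: float = 5.0, seed: int = 0,
                       perplexity: float = 30.0) -> Path:
    """t-SNE map of patient embeddings coloured by survival status at the
    horizon (censored-before-horizon patients shown in grey)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    X = embeddings.values
    perplexity = min(perplexity, max(2.0, (X.shape[0] - 1) / 3))
    coords = TSNE(n_components=2, random_state=seed,
                  perplexity=perplexity, init="pca").fit_transform(X)
    died = (outcomes.event == 1) & (outcomes.time <= horizon)
    alive = outcomes.time > horizon
    unknown = ~died & ~alive

    fig, ax = plt.subplots(figsize=(5, 4))
    for mask, label, color in ((alive, f"alive at {horizon:g}", "tab:blue"),
                               (died, f"died by {horizon:g}", "tab:red"),
                               (unknown, "censored early", "lightgrey")):
        if mask.any():
            ax.scatter(coords[mask, 0], coords[mask, 1], s=12, c=color,
                       label=label, alpha=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
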