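"""Minimal plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .stats import KMLogrankResult  # noqa: E402


def plot_km(result: KMLogrankResult, path: str) -> None:
    """Kaplan-Meier curves per subtype with the log-rank p annotated."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, kmf in result.curves.items():
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank chi2 = {result.chi2:.2f}, p = {result.p:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_box(distributions: dict[str, pd.DataFrame], metric: str,
                    path: str) -> None:
    """Boxplot of a resampling metric across models."""
    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(distributions)
    ax.boxplot([distributions[n][metric] for n in names], tick_labels=names)
    ax.set_ylabel(metric.upper())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_enrichment_heatmap(features, labels, selected: list[str],
                            path: str) -> None:
    """Heatmap of z-scored selected features, samples ordered by subtype."""
    z = features.standardized().frame[selected]
    order = np.argsort(np.asarray(labels))
    fig, ax = plt.subplots(figsize=(7, max(3, 0.12 * len(selected))))
    im = ax.imshow(z.iloc[order].T, aspect="auto", cmap="RdYlGn_r",
                   vmin=-2.5, vmax=2.5)
    ax.set_xlabel("samples (ordered by subtype)")
    ax.set_yticks(range(len(selected)))
    ax.set_yticklabels(selected, fontsize=5)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
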