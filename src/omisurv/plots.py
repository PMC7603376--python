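"""Basic figures: Kaplan-Meier curves, t-SNE scatter, Shapley summary bars.

Cosmetic only — nothing downstream consumes these. All functions take a
matplotlib Axes-free path-out interface and use the Agg backend.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def km_plot(comparison, path, title="Kaplan-Meier by subtype"):
    """Step plot of each group's survival curve with the log-rank p annotated."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, (grid, surv) in sorted(comparison.km_curves.items()):
        ax.step(grid, surv, where="post", label=f"subtype {group} (n={comparison.group_sizes[group]})")
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{title}\nlog-rank p = {comparison.p_value:.3g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def tsne_plot(embedding, labels, path, title="t-SNE of the integration matrix"):
    fig, ax = plt.subplots(figsize=(5, 4.5))
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        m = labels == lab
        ax.scatter(embedding[m, 0], embedding[m, 1], s=8, label=f"subtype {lab}")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def shap_summary_plot(attribution, path, top_n=10):
    """Horizontal bars of mean |Shapley value| for the top proteins."""
    ranking = attribution.mean_abs.head(top_n)[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.4 * top_n + 1))
    ax.barh(ranking.index, ranking.to_numpy())
    ax.set_xlabel("mean |Shapley value|")
    ax.set_title(f"protein attribution ({attribution.preset})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
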