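"""Score-plot and ROC figures.

Thin matplotlib wrappers for the figures practitioners make from these
models: 2D/3D latent-score scatter plots colored by class, and ROC curves
annotated with the AUC.  Each function writes a file when ``path`` is given
and always returns the figure.
"""

from __future__ import annotations

import numpy as np

from .containers import CLASS_LABELS

_COLORS = {"CO": "tab:blue", "CRC": "tab:red"}


def score_plot(scores, labels, explained=None, path=None, title="Score plot"):
    """Scatter of the first two (or three) latent scores by class.

    ``explained`` optionally gives per-component variance fractions for the
    axis labels; with three or more score columns a 3D panel is drawn.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    three_d = scores.shape[1] >= 3
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d" if three_d else None)

    def axis_name(a):
        if explained is not None and a < len(explained):
            return f"component {a + 1} ({100 * explained[a]:.2f}%)"
        return f"component {a + 1}"

    for cls in CLASS_LABELS:
        sel = labels == cls
        pts = [scores[sel, 0], scores[sel, 1]] + ([scores[sel, 2]] if three_d else [])
        ax.scatter(*pts, label=cls, color=_COLORS[cls], alpha=0.8)
    ax.set_xlabel(axis_name(0))
    ax.set_ylabel(axis_name(1))
    if three_d:
        ax.set_zlabel(axis_name(2))
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def roc_plot(roc_points, auc, path=None, title="ROC curve"):
    """ROC curve from the threshold-sweep points of :func:`roc_auc`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc_points["fpr"], roc_points["tpr"], drawstyle="steps-post", lw=2)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{title} (AUC = {auc:.2f})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
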