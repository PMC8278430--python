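"""Minimal ROC plotting (SVG/PNG) with the chance diagonal."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .roc import RocCurve, auc


def plot_roc_curves(curves: dict[str, RocCurve], path) -> None:
    """Render one axes with every named curve plus the AUC-0.5 diagonal."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC {auc(curve):.3f})")
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
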