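"""Static matplotlib plots for the evaluation panel (coordinate tables are primary)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .metrics import DecisionCurve


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=(5, 4))


def plot_roc(y_binary: np.ndarray, scores: dict[str, np.ndarray], path: str | Path) -> None:
    """One-vs-rest ROC curves for several score vectors on the same patients."""
    from sklearn.metrics import roc_curve

    fig, ax = _axes()
    for name, s in scores.items():
        fpr, tpr, _ = roc_curve(y_binary, s)
        ax.plot(fpr, tpr, label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_calibration(curve, path: str | Path) -> None:
    """Apparent and bias-corrected calibration curves against the diagonal."""
    fig, ax = _axes()
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.plot(curve["predicted"], curve["observed_apparent"], "-o", ms=3, label="apparent")
    ax.plot(curve["predicted"], curve["observed_corrected"], "-s", ms=3, label="bias-corrected")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed fraction")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_dca(curve: DecisionCurve, path: str | Path) -> None:
    """Net benefit of the model against treat-all and treat-none policies."""
    fig, ax = _axes()
    ax.plot(curve.thresholds, curve.net_benefit_model, label="model")
    ax.plot(curve.thresholds, curve.net_benefit_all, label="treat all")
    ax.plot(curve.thresholds, curve.net_benefit_none, "k--", lw=0.8, label="treat none")
    ax.set_ylim(bottom=max(-0.05, curve.net_benefit_model.min() - 0.02))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
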