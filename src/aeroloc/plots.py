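"""Diagnostic figures for validation runs (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .validate import PairedRetrieval, euclidean_uncertainty

__all__ = ["plot_retrieval_vs_truth", "plot_per_label_boxes"]


def _require_pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_retrieval_vs_truth(
    pairs: list[PairedRetrieval],
    out: str | Path,
    per_axis_sigma: float = 5.0,
) -> Path:
    """Four-panel retrieval-vs-truth scatter: distance from array center,
    height, and the two horizontal axes, with one-to-one lines and the
    truth-sensor uncertainty band."""
    plt = _require_pyplot()
    ret = np.array([p.retrieval for p in pairs])
    tru = np.array([p.truth for p in pairs])
    panels = [
        ("Euclidean distance (m)", np.linalg.norm(tru, axis=1),
         np.linalg.norm(ret, axis=1), euclidean_uncertainty(per_axis_sigma)),
        ("height AGL (m)", tru[:, 2], ret[:, 2], per_axis_sigma),
        ("x (m)", tru[:, 0], ret[:, 0], per_axis_sigma),
        ("y (m)", tru[:, 1], ret[:, 1], per_axis_sigma),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, (label, x, y, band) in zip(axes.ravel(), panels):
        ax.scatter(x, y, s=12, alpha=0.7)
        lims = [min(x.min(), y.min()), max(x.max(), y.max())]
        ax.plot(lims, lims, "k-", lw=1)
        ax.plot(lims, [v + band for v in lims], "k--", lw=0.8)
        ax.plot(lims, [v - band for v in lims], "k--", lw=0.8)
        ax.set_xlabel(f"truth {label}")
        ax.set_ylabel(f"retrieved {label}")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def plot_per_label_boxes(pairs: list[PairedRetrieval], out: str | Path) -> Path:
    """Per-call-type error boxplots (Tukey whiskers, outliers marked)."""
    plt = _require_pyplot()
    labels = sorted({p.label for p in pairs})
    panels = [
        ("Euclidean error (m)", lambda p: p.euclidean_error),
        ("|z error| (m)", lambda p: abs(p.errors[2])),
        ("|x error| (m)", lambda p: abs(p.errors[0])),
        ("|y error| (m)", lambda p: abs(p.errors[1])),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    for ax, (title, fn) in zip(axes.ravel(), panels):
        data = [[fn(p) for p in pairs if p.label == lab] for lab in labels]
        ax.boxplot(data, tick_labels=labels, whis=1.5,
                   flierprops={"marker": ".", "markerfacecolor": "red",
                               "markeredgecolor": "red"})
        ax.set_ylabel(title)
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
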