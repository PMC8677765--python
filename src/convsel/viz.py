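"""Small plotting helpers for the standard figures.

All functions write a PNG and return the path; they are conveniences over
matplotlib, not an analysis surface.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_accuracy_vs_units", "plot_tuning_curves", "plot_si_vs_counts"]


def plot_accuracy_vs_units(accuracy: pd.DataFrame, path) -> str:
    """Mean +- sd decoding accuracy against unit count, one line per
    population (expects the DetectionResult.accuracy table)."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for pop, sub in accuracy.groupby("population"):
        g = sub.groupby("n_units")["accuracy"]
        m, s = g.mean(), g.std()
        ax.errorbar(m.index, m.values, yerr=s.values, marker="o", capsize=3, label=pop)
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("number of units")
    ax.set_ylabel("balanced accuracy")
    ax.set_ylim(0.3, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_tuning_curves(tunings, path, max_units: int = 40) -> str:
    """Per-yaw mean responses of viewpoint-classified units, colored by
    category (expects a list of ViewpointTuning)."""
    colors = {
        "invariant": "tab:blue", "specific": "tab:red",
        "mirror_symmetric": "tab:green", "none": "lightgray",
    }
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    seen = set()
    for t in tunings[:max_units]:
        yaws = sorted(t.class_means, key=lambda c: float(
            "".join(ch for ch in c if ch in "+-0123456789") or 0))
        y = [t.class_means[c] for c in yaws]
        ax.plot(
            range(len(yaws)), y, color=colors.get(t.category, "k"), alpha=0.6,
            label=t.category if t.category not in seen else None,
        )
        seen.add(t.category)
    ax.set_xticks(range(len(yaws)), yaws, fontsize=7)
    ax.set_xlabel("viewpoint class")
    ax.set_ylabel("mean response")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_si_vs_counts(per_class_si: dict, per_class_counts: dict, path) -> str:
    """Class-level silhouette vs selective-unit count scatter."""
    fig, ax = plt.subplots(figsize=(4.0, 3.2))
    for c in sorted(per_class_si):
        ax.scatter(per_class_si[c], per_class_counts[c], s=25)
        ax.annotate(c, (per_class_si[c], per_class_counts[c]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("silhouette index (class mean)")
    ax.set_ylabel("selective units")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
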