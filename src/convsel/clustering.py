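"""Representational clustering of final-layer responses.

Stimulus-by-unit response matrices are embedded by PCA, and the consistency
of class clustering is quantified by a silhouette index

    SI_i = (b_i - a_i) / max(a_i, b_i)

where, in the centroid-based variant used here ("paper" mode), a_i is the
Euclidean distance from point i to its own class centroid and b_i is the
mean distance from that centroid to the other class centroids.  The classic
Rousseeuw per-point silhouette is available as a sensitivity check
("classic" mode, via scikit-learn).  Class-level silhouette means are then
correlated (Pearson) with the number of selective units found per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .net import ResponseTable

__all__ = [
    "ClusterMetrics",
    "pca_embed",
    "silhouette_index",
    "selectivity_vs_clustering",
]


@dataclass
class ClusterMetrics:
    embedding: np.ndarray  # points x components
    explained_variance: np.ndarray  # fraction per component, non-increasing
    per_point_si: np.ndarray | None = None
    per_class_si: dict[str, float] | None = None
    pearson_r_vs_counts: float | None = None


def pca_embed(table: ResponseTable | np.ndarray, n_components: int | None = None) -> ClusterMetrics:
    """Mean-centered projection onto orthonormal principal axes.

    n_components=None keeps every available component (min(n_points - 1,
    n_features)); requesting more than the rank truncates with a warning.
    """
    x = table.values if isinstance(table, ResponseTable) else np.asarray(table)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_comp
    elif n_components > max_comp:
        import warnings

        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_comp}; truncating"
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(x.astype(np.float64))
    return ClusterMetrics(
        embedding=emb, explained_variance=pca.explained_variance_ratio_
    )


def silhouette_index(
    points: np.ndarray, labels, mode: str = "paper"
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-point SI and per-class means.

    mode "paper": centroid-based distances as described above; mode
    "classic": standard per-point silhouette (mean intra-point distance vs
    nearest-cluster mean distance).
    """
    pts = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes (inter-class distance undefined)")
    if mode == "classic":
        from sklearn.metrics import silhouette_samples

        si = silhouette_samples(pts, labels)
    elif mode == "paper":
        centroids = {c: pts[labels == c].mean(axis=0) for c in classes}
        si = np.empty(len(pts))
        for c in classes:
            mask = labels == c
            own = centroids[c]
            a = np.linalg.norm(pts[mask] - own, axis=1)
            b = np.mean([np.linalg.norm(own - centroids[o]) for o in classes if o != c])
            with np.errstate(divide="ignore", invalid="ignore"):
                si[mask] = (b - a) / np.maximum(a, b)
            si[mask & np.isnan(si)] = 0.0  # a = b = 0: point on coincident centroids
    else:
        raise ValueError(f"unknown mode {mode!r}")
    per_class = {c: float(si[labels == c].mean()) for c in classes}
    return si, per_class


def selectivity_vs_clustering(
    per_class_si: dict[str, float], per_class_counts: dict[str, int]
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of class-level SI vs selective-unit count."""
    classes = sorted(per_class_si)
    if set(classes) != set(per_class_counts):
        raise ValueError("class keys of SI and counts differ")
    if len(classes) < 3:
        raise ValueError("need at least 3 classes")
    si = np.asarray([per_class_si[c] for c in classes], dtype=float)
    counts = np.asarray([per_class_counts[c] for c in classes], dtype=float)
    if si.std() == 0 or counts.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(si, counts)
    return float(r), float(p)


def emergence_threshold(
    per_class_si: dict[str, float], per_class_counts: dict[str, int]
) -> float:
    """Smallest class-level SI among classes with a nonzero selective-unit
    count — a generic detection threshold for selectivity emergence."""
    vals = [per_class_si[c] for c, n in per_class_counts.items() if n > 0]
    return float(min(vals)) if vals else float("nan")
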