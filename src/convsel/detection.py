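"""Face vs. non-face decoding from unit populations.

A linear SVM is trained on final-layer responses to held-out training images
(40 per class group by default, labels collapsed to face / non-face) and
evaluated on a further held-out test split (20 per class group).  Units are
resampled without replacement across trials; populations can be restricted
to face-selective, other-class-selective, any-selective or non-selective
units, or to a shuffled control whose sampled responses are permuted across
stimuli (chance-level reference).  Train/test stimuli are always disjoint
from the selection partition (the double-dipping guard is asserted at run
time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .net import ResponseTable
from .selectivity import SelectivityRecord

__all__ = [
    "DetectionConfig",
    "DetectionResult",
    "fit_linear_detector",
    "unit_populations",
    "detection_experiment",
    "population_ablation",
    "transform_transfer",
]

POPULATIONS = (
    "face_selective",
    "non_face_selective",
    "all_selective",
    "non_selective",
    "all_units",
    "shuffled_control",
)


@dataclass(frozen=True)
class DetectionConfig:
    unit_counts: tuple[int, ...] = (10,)
    n_trials: int = 100
    population: str = "face_selective"
    face_class: str = "face"
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}; one of {POPULATIONS}")


@dataclass
class DetectionResult:
    accuracy: pd.DataFrame  # columns: population, n_units, trial, accuracy

    def summary(self) -> pd.DataFrame:
        g = self.accuracy.groupby(["population", "n_units"])["accuracy"]
        return g.agg(["mean", "std", "count"]).reset_index()


def fit_linear_detector(features: np.ndarray, binary_labels: Sequence, C: float = 1.0) -> SVC:
    """Linear max-margin classifier (SVC, linear kernel, fixed C).

    Class weights are balanced: the face class contributes one training image
    per group while the non-face pool contributes one per non-face group, so
    without reweighting the margin would be dominated by the majority class.
    """
    y = np.asarray(binary_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(kernel="linear", C=C, class_weight="balanced")
    clf.fit(np.asarray(features, dtype=np.float64), y)
    return clf


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls; 0.5 is chance however unbalanced the split."""
    accs = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(accs))


def unit_populations(
    per_class_selective: Mapping[str, np.ndarray],
    n_units: int,
    face_class: str = "face",
) -> dict[str, np.ndarray]:
    """Flat unit-index arrays for each named population.

    per_class_selective maps class name -> boolean mask (n_units,) of units
    selective to that class.  face/non-face-selective/non-selective form a
    disjoint partition (units selective to several classes count once, face
    taking precedence).
    """
    face = np.asarray(per_class_selective[face_class], dtype=bool)
    any_sel = np.zeros(n_units, dtype=bool)
    for m in per_class_selective.values():
        any_sel |= np.asarray(m, dtype=bool)
    return {
        "face_selective": np.flatnonzero(face),
        "non_face_selective": np.flatnonzero(any_sel & ~face),
        "all_selective": np.flatnonzero(any_sel),
        "non_selective": np.flatnonzero(~any_sel),
        "all_units": np.arange(n_units),
        "shuffled_control": np.flatnonzero(face),  # responses permuted at sampling
    }


def _binary_labels(class_labels: Sequence[str], face_class: str) -> np.ndarray:
    return np.asarray([c == face_class for c in class_labels], dtype=int)


def _guard_double_dipping(stimuli, table: ResponseTable) -> tuple[np.ndarray, np.ndarray]:
    tags = np.asarray(stimuli.partition_tags)
    train = tags == "train"
    test = tags == "test"
    sel_ids = {s for s, t in zip(stimuli.stimulus_ids, tags) if t == "selection"}
    used = {s for s, t in zip(stimuli.stimulus_ids, tags) if t in ("train", "test")}
    if sel_ids & used:
        raise ValueError("selection images leak into the train/test split")
    if not train.any() or not test.any():
        raise ValueError("stimulus set lacks a train or test partition")
    return train, test


def detection_experiment(
    table: ResponseTable,
    stimuli,
    per_class_selective: Mapping[str, np.ndarray],
    cfg: DetectionConfig = DetectionConfig(),
) -> DetectionResult:
    """Face/non-face decoding accuracy over unit counts and trials."""
    train_mask, test_mask = _guard_double_dipping(stimuli, table)
    y = _binary_labels(stimuli.class_labels, cfg.face_class)
    pools = unit_populations(per_class_selective, table.n_units, cfg.face_class)
    pool = pools[cfg.population]
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for n in cfg.unit_counts:
        if n > pool.size:
            raise ValueError(
                f"unit_count {n} exceeds population {cfg.population!r} size {pool.size}"
            )
        for trial in range(cfg.n_trials):
            units = rng.choice(pool, size=n, replace=False)
            feats = table.values[:, units].astype(np.float64)
            if cfg.population == "shuffled_control":
                feats = feats.copy()
                for k in range(n):
                    feats[:, k] = feats[rng.permutation(feats.shape[0]), k]
            clf = fit_linear_detector(feats[train_mask], y[train_mask], C=cfg.svm_c)
            acc = _balanced_accuracy(y[test_mask], clf.predict(feats[test_mask]))
            rows.append(
                {"population": cfg.population, "n_units": n, "trial": trial, "accuracy": acc}
            )
    return DetectionResult(accuracy=pd.DataFrame(rows))


def population_ablation(
    table: ResponseTable,
    stimuli,
    per_class_selective: Mapping[str, np.ndarray],
    cfg: DetectionConfig = DetectionConfig(),
    populations: Sequence[str] = (
        "all_selective", "non_face_selective", "face_selective", "non_selective",
    ),
) -> DetectionResult:
    """Decoding accuracy of the four unit populations at matched unit counts.

    Empty populations are recorded as missing rows, not errors.
    """
    frames = []
    pools = unit_populations(per_class_selective, table.n_units, cfg.face_class)
    for popname in populations:
        pool = pools[popname]
        counts = [n for n in cfg.unit_counts if n <= pool.size]
        if not counts:
            frames.append(
                pd.DataFrame(
                    [{"population": popname, "n_units": np.nan, "trial": np.nan, "accuracy": np.nan}]
                )
            )
            continue
        sub = DetectionConfig(
            unit_counts=tuple(counts), n_trials=cfg.n_trials, population=popname,
            face_class=cfg.face_class, svm_c=cfg.svm_c, seed=cfg.seed,
        )
        frames.append(detection_experiment(table, stimuli, per_class_selective, sub).accuracy)
    return DetectionResult(accuracy=pd.concat(frames, ignore_index=True))


def transform_transfer(
    table_train: ResponseTable,
    stimuli_train,
    tables_by_level: Mapping[float, ResponseTable],
    labels_by_level: Mapping[float, Sequence[str]],
    unit_cols: np.ndarray,
    face_class: str = "face",
) -> pd.DataFrame:
    """Train on canonical-view images, test on transform variants.

    The classifier is fit once on the train partition of the canonical set
    (restricted to ``unit_cols``, typically the face-selective units) and
    evaluated on the full response table of each transform level.
    """
    if len(tables_by_level) == 0:
        raise ValueError("empty transform level list")
    train_mask = np.asarray(stimuli_train.partition_tags) == "train"
    if not train_mask.any():
        raise ValueError("canonical set has no train partition")
    y_train = _binary_labels(stimuli_train.class_labels, face_class)[train_mask]
    clf = fit_linear_detector(
        table_train.values[np.flatnonzero(train_mask)][:, unit_cols], y_train
    )
    rows = []
    for lv in sorted(tables_by_level):
        t = tables_by_level[lv]
        y = _binary_labels(labels_by_level[lv], face_class)
        pred = clf.predict(t.values[:, unit_cols].astype(np.float64))
        rows.append(
            {"level": lv, "n_test": len(y), "accuracy": _balanced_accuracy(y, pred)}
        )
    return pd.DataFrame(rows)
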