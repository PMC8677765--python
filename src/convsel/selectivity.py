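"""Class-selective units and the face-selectivity index (FSI).

A unit is selective to a target class when its mean response to that class is
significantly higher than to every other class (two-sided Wilcoxon rank-sum,
uncorrected, alpha 0.001 by default) and strictly greatest in the mean.  The
degree of face tuning is measured by the d'-like index

    FSI = (Rbar_face - Rbar_nonface) / sqrt((var_face + var_nonface) / 2)

where the non-face pool is every non-face class (scrambled faces included by
default).  Null calibration is by label permutation: shuffling stimulus
labels must drive the selection rate to (at most) the per-comparison alpha
and the FSI distribution to zero mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .net import NetworkModel, ResponseTable, UnitIndex, extract_responses

__all__ = [
    "SelectionConfig",
    "SelectivityRecord",
    "rank_sum_test",
    "zscore_responses",
    "compute_fsi",
    "fsi_table",
    "find_selective_units",
    "selectivity_frame",
    "shuffled_fsi_null",
    "layerwise_selectivity",
    "generalization_test",
    "FSI_REGISTRY",
]

_EXACT_N = 12  # combined sample size up to which the exact enumeration runs


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.001
    test_sidedness: str = "two-sided"
    nonface_pool: tuple[str, ...] | None = None  # None = all non-target classes
    shuffle_reps: int = 1000
    seed: int = 0
    p_method: str = "auto"  # auto | exact | asymptotic

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SelectivityRecord:
    unit: UnitIndex
    preferred_class: str
    pairwise_p: dict[str, float]
    fsi: float
    z_profile: dict[str, float]
    is_selective: bool


# ---------------------------------------------------------------------------
# rank-sum test


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray, sidedness: str) -> float:
    """Exact permutation p for the rank-sum statistic, tie-aware (midranks).

    Enumerates every assignment of the pooled midranks to the x positions and
    counts assignments at least as extreme as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mu = nx * (len(pooled) + 1) / 2.0
    count = 0
    total = comb(len(pooled), nx)
    for idx in combinations(range(len(pooled)), nx):
        w = ranks[list(idx)].sum()
        if sidedness == "two-sided":
            hit = abs(w - mu) >= abs(w_obs - mu) - 1e-12
        elif sidedness == "greater":
            hit = w >= w_obs - 1e-12
        else:  # less
            hit = w <= w_obs + 1e-12
        count += hit
    return count / total


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: str = "two-sided",
    method: str = "auto",
) -> float:
    """Wilcoxon rank-sum p-value.

    method='auto' uses exact enumeration when the combined sample size is at
    most 12 (matching a brute-force permutation of midranks even under ties)
    and the tie-corrected normal approximation with continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if method == "auto":
        method = "exact" if x.size + y.size <= _EXACT_N else "asymptotic"
    if method == "exact":
        return float(_exact_ranksum_p(x, y, sidedness))
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values tied: no evidence either way
    res = stats.mannwhitneyu(x, y, alternative=sidedness, method="asymptotic")
    return float(res.pvalue)


def _pairwise_p_matrix(
    target_vals: np.ndarray, other_vals: np.ndarray, sidedness: str
) -> np.ndarray:
    """Vectorized asymptotic rank-sum p per unit (columns)."""
    # units with all values tied across both groups get p = 1
    pooled = np.concatenate([target_vals, other_vals], axis=0)
    tied = np.ptp(pooled, axis=0) == 0
    p = np.ones(target_vals.shape[1])
    if np.all(tied):
        return p
    cols = ~tied
    res = stats.mannwhitneyu(
        target_vals[:, cols], other_vals[:, cols], alternative=sidedness,
        method="asymptotic", axis=0,
    )
    p[cols] = res.pvalue
    return p


# ---------------------------------------------------------------------------
# z-scoring and FSI


def zscore_responses(table: ResponseTable) -> tuple[ResponseTable, np.ndarray]:
    """Per-unit z-scores across stimuli; returns (table, constant_unit_mask).

    Constant units cannot be z-scored; they are flagged and their z columns
    set to NaN (they are excluded from z-profiles downstream).
    """
    vals = table.values.astype(np.float64)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    # tolerance absorbs rounding of the mean of a bitwise-constant column
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
    z = np.full_like(vals, np.nan)
    ok = ~constant
    z[:, ok] = (vals[:, ok] - mu[ok]) / sd[ok]
    zt = ResponseTable(
        layer=table.layer,
        values=z,
        unit_order=table.unit_order,
        stimulus_ids=list(table.stimulus_ids),
    )
    return zt, constant


def compute_fsi(face_responses: Sequence[float], nonface_responses: Sequence[float]) -> float:
    """(Rbar_f - Rbar_nf) / sqrt((var_f + var_nf)/2); sample variance (n-1)."""
    f = np.asarray(face_responses, dtype=float)
    nf = np.asarray(nonface_responses, dtype=float)
    if f.size < 2 or nf.size < 2:
        raise ValueError("need at least 2 responses per group")
    num = f.mean() - nf.mean()
    denom = np.sqrt((f.var(ddof=1) + nf.var(ddof=1)) / 2.0)
    if denom == 0:
        if num == 0:
            return 0.0
        return float(np.sign(num) * np.inf)
    return float(num / denom)


def fsi_table(
    values: np.ndarray, labels: Sequence[str], target_class: str,
    nonface_pool: Iterable[str] | None = None,
) -> np.ndarray:
    """Vectorized FSI for every unit (column) of a response matrix."""
    labels = np.asarray(labels)
    fmask = labels == target_class
    if nonface_pool is None:
        nmask = ~fmask
    else:
        nmask = np.isin(labels, list(nonface_pool))
    f = values[fmask].astype(np.float64)
    nf = values[nmask].astype(np.float64)
    num = f.mean(axis=0) - nf.mean(axis=0)
    denom = np.sqrt((f.var(axis=0, ddof=1) + nf.var(axis=0, ddof=1)) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fsi = num / denom
    fsi[(denom == 0) & (num == 0)] = 0.0
    fsi[(denom == 0) & (num != 0)] = np.sign(num[(denom == 0) & (num != 0)]) * np.inf
    return fsi


# the Eq.-1 style contrast is the default; alternatives are pluggable
FSI_REGISTRY = {
    "dprime": compute_fsi,
    "ratio": lambda f, nf: float(
        (np.mean(f) - np.mean(nf)) / (np.mean(f) + np.mean(nf))
    ),
}


# ---------------------------------------------------------------------------
# selection rule


def selectivity_frame(
    table: ResponseTable,
    labels: Sequence[str],
    target_class: str,
    cfg: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Per-unit selectivity statistics as a DataFrame (vectorized).

    Columns: channel, row, col, preferred_class, fsi, is_selective, and one
    p_<class> column per non-target class (uncorrected two-sided rank-sum).
    """
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))
    if target_class not in classes:
        raise ValueError(f"target class {target_class!r} absent from labels")
    vals = table.values.astype(np.float64)
    tmask = labels == target_class
    class_means = {c: vals[labels == c].mean(axis=0) for c in classes}
    mean_stack = np.stack([class_means[c] for c in classes])
    preferred = np.asarray(classes)[np.argmax(mean_stack, axis=0)]
    selective = np.ones(table.n_units, dtype=bool)
    pcols: dict[str, np.ndarray] = {}
    for c in classes:
        if c == target_class:
            continue
        p = _pairwise_p_matrix(vals[tmask], vals[labels == c], cfg.test_sidedness)
        pcols[f"p_{c}"] = p
        selective &= (p < cfg.alpha) & (class_means[target_class] > class_means[c])
    fsi = fsi_table(vals, labels, target_class, cfg.nonface_pool)
    df = pd.DataFrame(
        {
            "channel": table.unit_order[:, 0],
            "row": table.unit_order[:, 1],
            "col": table.unit_order[:, 2],
            "preferred_class": preferred,
            "fsi": fsi,
            "is_selective": selective,
        }
    )
    for k, v in pcols.items():
        df[k] = v
    return df


def find_selective_units(
    table: ResponseTable,
    labels: Sequence[str],
    target_class: str,
    cfg: SelectionConfig = SelectionConfig(),
) -> list[SelectivityRecord]:
    """SelectivityRecord for every unit (is_selective marks the hits).

    Selective to target_class iff, against every other class, the two-sided
    rank-sum p < alpha (uncorrected) and the target mean is strictly
    greatest.
    """
    df = selectivity_frame(table, labels, target_class, cfg)
    zt, constant = zscore_responses(table)
    labels_arr = np.asarray(labels)
    classes = list(dict.fromkeys(labels_arr))
    zvals = np.where(np.isnan(zt.values), 0.0, zt.values)  # constant units excluded below
    zmeans = {c: zvals[labels_arr == c].mean(axis=0) for c in classes}
    pcols = [c for c in df.columns if c.startswith("p_")]
    records = []
    for j in range(table.n_units):
        zp = {} if constant[j] else {c: float(zmeans[c][j]) for c in classes}
        records.append(
            SelectivityRecord(
                unit=table.unit_index(j),
                preferred_class=str(df["preferred_class"].iloc[j]),
                pairwise_p={c[2:]: float(df[c].iloc[j]) for c in pcols},
                fsi=float(df["fsi"].iloc[j]),
                z_profile=zp,
                is_selective=bool(df["is_selective"].iloc[j]),
            )
        )
    return records


def records_to_csv(records: list[SelectivityRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "layer": r.unit.layer, "channel": r.unit.channel,
            "row": r.unit.row, "col": r.unit.col,
            "preferred_class": r.preferred_class, "fsi": r.fsi,
            "is_selective": r.is_selective,
        }
        row.update({f"p_{k}": v for k, v in r.pairwise_p.items()})
        row.update({f"z_{k}": v for k, v in r.z_profile.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# null calibration and summaries


def shuffled_fsi_null(
    table: ResponseTable,
    labels: Sequence[str],
    reps: int,
    seed: int = 0,
    target_class: str = "face",
    unit_cols: np.ndarray | None = None,
) -> np.ndarray:
    """FSI distribution under uniform permutation of stimulus labels.

    Returns an array (reps, n_units); with exchangeable labels its mean is 0
    up to Monte-Carlo error.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels = np.asarray(labels)
    vals = table.values if unit_cols is None else table.values[:, unit_cols]
    rng = np.random.default_rng(seed)
    out = np.empty((reps, vals.shape[1]))
    for r in range(reps):
        perm = rng.permutation(len(labels))
        out[r] = fsi_table(vals, labels[perm], target_class)
    return out


def layerwise_selectivity(
    net: NetworkModel,
    stimuli,
    target_class: str = "face",
    cfg: SelectionConfig = SelectionConfig(),
    layers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count and percentage of target-selective units in each conv layer."""
    if layers is None:
        layers = net.conv_layer_names
    sel = stimuli.partition("selection")
    labels = sel.class_labels
    tables = extract_responses(net, sel, layers=layers)
    rows = []
    for t in tables:
        df = selectivity_frame(t, labels, target_class, cfg)
        hits = df["is_selective"]
        fsis = df.loc[hits, "fsi"]
        rows.append(
            {
                "layer": t.layer,
                "n_units": t.n_units,
                "n_selective": int(hits.sum()),
                "pct_selective": 100.0 * hits.sum() / t.n_units,
                "fsi_mean": float(fsis.mean()) if hits.any() else np.nan,
                "fsi_median": float(fsis.median()) if hits.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def generalization_test(
    net: NetworkModel,
    records: list[SelectivityRecord],
    novel_sets: Sequence,
    selection_ids: Iterable[str],
    face_class: str = "face",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Do the selected units respond more to *novel* faces than non-faces?

    Each novel set must be disjoint from the selection images (double-dipping
    guard).  Per set, the mean selective-unit response per image is compared
    between novel faces and novel non-faces with a one-sided rank-sum test.
    """
    sel_units = [r.unit for r in records if r.is_selective]
    if not sel_units:
        raise ValueError("no selective units supplied")
    selection_ids = set(selection_ids)
    rows = []
    for k, ns in enumerate(novel_sets):
        if len(ns) == 0:
            raise ValueError("empty novel set")
        overlap = selection_ids & set(ns.stimulus_ids)
        if overlap:
            raise ValueError(
                f"novel set {k} overlaps the selection partition: {sorted(overlap)[:3]}..."
            )
        table = extract_responses(net, ns, layers=[sel_units[0].layer])[0]
        cols = [table.flat_index(u) for u in sel_units]
        mean_resp = table.values[:, cols].mean(axis=1)
        labels = np.asarray(ns.class_labels)
        fmask = labels == face_class
        if not fmask.any() or fmask.all():
            raise ValueError(f"novel set {k} needs both face and non-face images")
        p = rank_sum_test(mean_resp[fmask], mean_resp[~fmask], sidedness="greater")
        rows.append(
            {
                "set": k,
                "n_faces": int(fmask.sum()),
                "n_nonfaces": int((~fmask).sum()),
                "mean_face": float(mean_resp[fmask].mean()),
                "mean_nonface": float(mean_resp[~fmask].mean()),
                "p_one_sided": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
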