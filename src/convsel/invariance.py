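"""Viewpoint and transform tuning of face-selective units.

Units already identified as face-selective are classified by their tuning
over head-yaw classes (-90, -45, 0, 45, 90 degrees):

* viewpoint-invariant — responses do not differ across yaw classes (one-way
  ANOVA, Bonferroni-adjusted p > alpha with n = 5);
* viewpoint-specific — one yaw's mean is significantly higher than every
  other yaw (pairwise two-group ANOVA, adjusted p < alpha);
* mirror-symmetric — a specific-type tuning whose two peaks are the mirror
  pair {-theta, +theta} (each significantly above the remaining yaws, the
  pair itself not significantly different).

The invariance index of a unit is 1 / std of its per-yaw mean responses
(sample std, n-1); flat tuning maps to +inf.  The inversion effect compares
responses to upright vs 180-degree-rotated versions of the same exemplars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .net import ResponseTable, UnitIndex
from .selectivity import SelectivityRecord, rank_sum_test

__all__ = [
    "ViewpointTuning",
    "oneway_anova",
    "classify_viewpoint_units",
    "invariance_index",
    "inversion_effect",
]


@dataclass
class ViewpointTuning:
    unit: UnitIndex
    class_means: dict[str, float]
    anova_p: float
    category: str  # invariant | specific | mirror_symmetric | none
    invariance_index: float  # +inf marker when std of means is 0


def oneway_anova(groups: Sequence[Sequence[float]]) -> float:
    """Classical one-way ANOVA F-test p-value.

    Degenerate inputs follow fixed conventions: zero within-group variance
    with equal means gives p = 1 (no evidence of a difference); zero
    within-group variance with unequal means gives p = 0.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if within == 0:
        means = [a.mean() for a in arrs]
        return 1.0 if np.ptp(means) == 0 else 0.0
    res = stats.f_oneway(*arrs)
    return float(res.pvalue)


def invariance_index(class_means: Sequence[float]) -> float:
    """1 / sample std (n-1) of the per-class mean responses; inf when flat."""
    m = np.asarray(class_means, dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 class means")
    sd = m.std(ddof=1)
    return float("inf") if sd == 0 else float(1.0 / sd)


def _adj(p: float, n: int) -> float:
    return min(1.0, p * n)


def classify_viewpoint_units(
    table: ResponseTable,
    yaw_labels: Sequence[str],
    alpha: float = 0.05,
    bonferroni_n: int = 5,
    yaw_values: dict[str, float] | None = None,
) -> list[ViewpointTuning]:
    """Tuning category for each unit in the table.

    yaw_labels gives the yaw class of each stimulus (row).  When yaw_values
    is omitted, labels of the form 'yaw+45' are parsed for the mirror-pair
    check.  Categories are mutually exclusive; units that are neither
    invariant nor specific are 'none'.
    """
    labels = np.asarray(yaw_labels)
    if len(labels) != table.values.shape[0]:
        raise ValueError("yaw_labels length does not match the response table")
    classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 yaw classes")
    if bonferroni_n is not None and len(classes) != bonferroni_n:
        raise ValueError(
            f"missing yaw class: expected {bonferroni_n} viewpoint classes, "
            f"found {len(classes)}"
        )
    if yaw_values is None:
        yaw_values = {}
        for c in classes:
            digits = "".join(ch for ch in c if ch in "+-0123456789")
            yaw_values[c] = float(digits) if digits else float("nan")
    masks = {c: labels == c for c in classes}
    if any(m.sum() < 2 for m in masks.values()):
        raise ValueError("every yaw class needs >= 2 stimuli")
    out: list[ViewpointTuning] = []
    for j in range(table.n_units):
        col = table.values[:, j].astype(float)
        groups = {c: col[masks[c]] for c in classes}
        means = {c: float(g.mean()) for c, g in groups.items()}
        p_anova = _adj(oneway_anova(list(groups.values())), bonferroni_n)
        inv_idx = invariance_index(list(means.values()))
        category = "none"
        if p_anova > alpha:
            category = "invariant"
        else:
            order = sorted(classes, key=lambda c: means[c], reverse=True)
            top = order[0]

            def beats(a: str, b: str) -> bool:
                p = _adj(oneway_anova([groups[a], groups[b]]), bonferroni_n)
                return p < alpha and means[a] > means[b]

            if all(beats(top, c) for c in classes if c != top):
                category = "specific"
            else:
                # mirror pair: top-2 are {-theta, +theta}, each above the rest,
                # and not significantly different from each other
                second = order[1]
                v1, v2 = yaw_values.get(top), yaw_values.get(second)
                if (
                    v1 is not None and v2 is not None
                    and np.isfinite(v1) and np.isfinite(v2)
                    and v1 == -v2 and v1 != 0
                ):
                    rest = [c for c in classes if c not in (top, second)]
                    pair_same = (
                        _adj(oneway_anova([groups[top], groups[second]]), bonferroni_n)
                        > alpha
                    )
                    if pair_same and all(
                        beats(top, c) and beats(second, c) for c in rest
                    ):
                        category = "mirror_symmetric"
        out.append(
            ViewpointTuning(
                unit=table.unit_index(j),
                class_means=means,
                anova_p=p_anova,
                category=category,
                invariance_index=inv_idx,
            )
        )
    return out


def tuning_to_frame(tunings: list[ViewpointTuning]) -> pd.DataFrame:
    rows = []
    for t in tunings:
        row = {
            "layer": t.unit.layer, "channel": t.unit.channel,
            "row": t.unit.row, "col": t.unit.col,
            "anova_p": t.anova_p, "category": t.category,
            "invariance_index": t.invariance_index,
        }
        row.update({f"mean_{k}": v for k, v in t.class_means.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def inversion_effect(
    records: list[SelectivityRecord],
    upright_table: ResponseTable,
    inverted_table: ResponseTable,
    upright_identities: Sequence[int] | None = None,
    inverted_identities: Sequence[int] | None = None,
) -> dict:
    """Upright vs inverted (180-degree) responses of the selective units.

    The two tables must hold responses to the same exemplars (paired by
    identity when identity lists are given).  Returns per-unit means and a
    one-sided rank-sum p across units for upright > inverted.
    """
    sel = [r.unit for r in records if r.is_selective]
    if not sel:
        raise ValueError("empty unit list")
    if upright_identities is not None or inverted_identities is not None:
        if list(upright_identities) != list(inverted_identities):
            raise ValueError("upright and inverted sets are not paired by identity")
    if upright_table.values.shape[0] != inverted_table.values.shape[0]:
        raise ValueError("upright and inverted sets differ in size (not paired)")
    cols = [upright_table.flat_index(u) for u in sel]
    up = upright_table.values[:, cols].mean(axis=0)
    inv = inverted_table.values[:, cols].mean(axis=0)
    p = rank_sum_test(up, inv, sidedness="greater")
    return {
        "per_unit_upright": up,
        "per_unit_inverted": inv,
        "mean_upright": float(up.mean()),
        "mean_inverted": float(inv.mean()),
        "p_one_sided": float(p),
    }
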