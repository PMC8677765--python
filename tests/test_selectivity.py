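"""Selectivity statistics: rank-sum test, z-scoring, FSI, selection rule."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from convsel.net import ResponseTable
from convsel.selectivity import (
    SelectionConfig,
    compute_fsi,
    find_selective_units,
    fsi_table,
    generalization_test,
    rank_sum_test,
    selectivity_frame,
    shuffled_fsi_null,
    zscore_responses,
)


def brute_force_ranksum_p(x, y, sidedness="two-sided"):
    """Enumerate every assignment of pooled midranks to the x slots."""
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    # midranks by explicit tie grouping
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mu = nx * (len(pooled) + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(len(pooled)), nx):
        w = ranks[list(idx)].sum()
        total += 1
        if sidedness == "two-sided":
            hits += abs(w - mu) >= abs(w_obs - mu) - 1e-12
        elif sidedness == "greater":
            hits += w >= w_obs - 1e-12
        else:
            hits += w <= w_obs + 1e-12
    return hits / total


class TestRankSum:
    def test_textbook_example(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_1(self):
        assert rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(3, 7))
        ny = int(rng.integers(3, 13 - nx))
        # integer draws force ties
        x = rng.integers(0, 5, nx).astype(float)
        y = rng.integers(0, 5, ny).astype(float)
        for side in ("two-sided", "greater", "less"):
            assert rank_sum_test(x, y, side) == pytest.approx(
                brute_force_ranksum_p(x, y, side), abs=1e-12
            )

    def test_asymptotic_close_to_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(40), rng.random(35) + 0.1
        p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def _table(values):
    values = np.asarray(values, dtype=np.float64)
    order = np.stack(
        [np.zeros(values.shape[1]), np.zeros(values.shape[1]), np.arange(values.shape[1])],
        axis=1,
    ).astype(np.int32)
    return ResponseTable("conv5", values, order, [f"s{i}" for i in range(values.shape[0])])


class TestZScore:
    def test_moments(self):
        t = _table(np.random.default_rng(0).random((50, 7)))
        z, const = zscore_responses(t)
        assert not const.any()
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-6)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1, atol=1e-6)

    def test_affine_invariance(self):
        v = np.random.default_rng(1).random((30, 3))
        z1, _ = zscore_responses(_table(v))
        z2, _ = zscore_responses(_table(3.5 * v + 2.0))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)

    def test_constant_unit_flagged(self):
        v = np.random.default_rng(2).random((20, 2))
        v[:, 1] = 4.2
        z, const = zscore_responses(_table(v))
        assert list(const) == [False, True]
        assert np.isnan(z.values[:, 1]).all()


class TestFSI:
    def test_hand_example(self):
        assert compute_fsi([1, 3], [0, 2]) == pytest.approx(1 / np.sqrt(2))

    def test_equal_means_zero(self):
        assert compute_fsi([1.0, 2.0], [2.0, 1.0]) == 0.0

    def test_antisymmetry(self):
        f, nf = [1.0, 3.0, 2.0], [0.5, 0.2, 0.9]
        assert compute_fsi(f, nf) == pytest.approx(-compute_fsi(nf, f))

    def test_zero_variance_markers(self):
        assert compute_fsi([2.0, 2.0], [2.0, 2.0]) == 0.0
        assert compute_fsi([3.0, 3.0], [1.0, 1.0]) == np.inf

    def test_affine_invariance_of_scale(self):
        rng = np.random.default_rng(3)
        f, nf = rng.random(20), rng.random(25)
        base = compute_fsi(f, nf)
        assert compute_fsi(5 * f, 5 * nf) == pytest.approx(base, rel=1e-12)
        # common additive shift leaves the index unchanged too
        assert compute_fsi(f + 7, nf + 7) == pytest.approx(base, rel=1e-9)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compute_fsi([1.0], [1.0, 2.0])


def _planted_table(rng, n_per_class=60, n_classes=6, n_units=4, planted_col=0):
    n = n_per_class * n_classes
    labels = np.repeat([f"c{k}" for k in range(n_classes)], n_per_class)
    labels = np.where(labels == "c0", "face", labels)
    vals = rng.normal(1.0, 0.1, (n, n_units))
    vals[labels == "face", planted_col] += 9.0
    return _table(vals), list(labels)


class TestSelectionRule:
    def test_planted_unit_selected(self):
        t, labels = _planted_table(np.random.default_rng(0))
        recs = find_selective_units(t, labels, "face")
        assert recs[0].is_selective
        assert recs[0].preferred_class == "face"
        assert all(p < 1e-6 for p in recs[0].pairwise_p.values())
        assert recs[0].fsi > 5

    def test_constant_unit_not_selected(self):
        v = np.random.default_rng(1).random((60, 2))
        v[:, 1] = 1.0
        labels = ["face"] * 30 + ["chair"] * 30
        recs = find_selective_units(_table(v), labels, "face")
        assert not recs[1].is_selective
        assert recs[1].pairwise_p["chair"] == 1.0

    def test_null_selection_rate_bounded(self):
        rng = np.random.default_rng(2)
        n_units = 2000
        vals = rng.normal(size=(120, n_units))
        labels = list(np.repeat(["face", "a", "b", "c"], 30))
        df = selectivity_frame(_table(vals), labels, "face", SelectionConfig(alpha=0.01))
        rate = df["is_selective"].mean()
        assert rate <= 0.01 + 3 * np.sqrt(0.01 / n_units)

    def test_absent_target_rejected(self):
        t, labels = _planted_table(np.random.default_rng(3))
        with pytest.raises(ValueError):
            selectivity_frame(t, labels, "zebra")


class TestShuffledNull:
    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(4)
        t = _table(rng.normal(1, 0.3, (120, 50)))
        labels = np.repeat(["face", "a", "b", "c"], 30)
        null = shuffled_fsi_null(t, labels, reps=200, seed=0)
        sem = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean()) < 3 * sem + 1e-3

    def test_planted_fsi_extreme_in_null(self):
        t, labels = _planted_table(np.random.default_rng(5), n_units=1)
        observed = fsi_table(t.values, labels, "face")[0]
        null = shuffled_fsi_null(t, labels, reps=500, seed=1)
        assert observed > null.max()

    def test_rep_validation(self):
        t, labels = _planted_table(np.random.default_rng(6))
        with pytest.raises(ValueError):
            shuffled_fsi_null(t, labels, reps=0)


class TestGeneralization:
    def test_planted_generalizes_and_guards(self, tiny_net, small_stim):
        sel = small_stim.partition("selection")
        import convsel

        table = convsel.extract_responses(tiny_net, sel, layers=["conv2"])[0]
        recs = find_selective_units(
            table, sel.class_labels, "face", SelectionConfig(alpha=0.05)
        )
        if not any(r.is_selective for r in recs):
            pytest.skip("no selective unit at this tiny scale")
        novel = small_stim.partition("train")
        df = generalization_test(
            tiny_net, recs, [novel], selection_ids=sel.stimulus_ids
        )
        assert df.shape[0] == 1 and 0 <= df["p_one_sided"].iloc[0] <= 1
        with pytest.raises(ValueError, match="overlap"):
            generalization_test(tiny_net, recs, [sel], selection_ids=sel.stimulus_ids)
        empty = novel.subset(np.zeros(len(novel), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            generalization_test(tiny_net, recs, [empty], selection_ids=sel.stimulus_ids)


class TestLayerwise:
    def test_all_zero_weights_gives_no_selectivity(self, tiny_arch, small_stim):
        import convsel
        from convsel.selectivity import layerwise_selectivity

        net = convsel.build_network(
            tiny_arch, convsel.InitConfig(seed=0, zero_bias=True)
        )
        for k in net.weights:
            net.weights[k] = np.zeros_like(net.weights[k])
        df = layerwise_selectivity(net, small_stim)
        assert (df["n_selective"] == 0).all()

    def test_percentages_consistent(self, tiny_net, small_stim):
        from convsel.selectivity import layerwise_selectivity

        df = layerwise_selectivity(
            tiny_net, small_stim, cfg=SelectionConfig(alpha=0.05)
        )
        assert list(df["layer"]) == ["conv1", "conv2"]
        np.testing.assert_allclose(
            df["pct_selective"], 100.0 * df["n_selective"] / df["n_units"]
        )


from hypothesis import given, settings, strategies as st

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    f=st.lists(finite, min_size=2, max_size=12),
    nf=st.lists(finite, min_size=2, max_size=12),
    shift=st.floats(-100, 100, allow_nan=False),
)
def test_fsi_antisymmetry_and_shift_property(f, nf, shift):
    a = compute_fsi(f, nf)
    b = compute_fsi(nf, f)
    if np.isfinite(a):
        assert a == pytest.approx(-b, rel=1e-9, abs=1e-9)
        shifted = compute_fsi(np.asarray(f) + shift, np.asarray(nf) + shift)
        # shift invariance degrades only with catastrophic cancellation
        assert shifted == pytest.approx(a, rel=1e-4, abs=1e-4)
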