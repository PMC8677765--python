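"""Face vs non-face decoding: protocol, populations, chance calibration."""

import numpy as np
import pandas as pd
import pytest

from convsel.detection import (
    DetectionConfig,
    detection_experiment,
    fit_linear_detector,
    population_ablation,
    transform_transfer,
    unit_populations,
)
from convsel.net import ResponseTable
from convsel.stimuli import StimulusSet


def _feature_stimulus(
    rng, n_units=30, n_informative=6, n_train_face=12, signal=2.0
):
    """A response table + stimulus set with planted face-coding units."""
    classes = ["face", "a", "b"]
    per_part = {"selection": 20, "train": n_train_face, "test": 10}
    labels, tags = [], []
    for cls in classes:
        for tag, k in per_part.items():
            labels += [cls] * k
            tags += [tag] * k
    n = len(labels)
    vals = rng.normal(size=(n, n_units))
    face = np.asarray(labels) == "face"
    vals[np.ix_(face, np.arange(n_informative))] += signal
    order = np.stack(
        [np.zeros(n_units), np.zeros(n_units), np.arange(n_units)], axis=1
    ).astype(np.int32)
    table = ResponseTable("conv5", vals, order, [f"s{i}" for i in range(n)])
    meta = pd.DataFrame(
        {"scale": 1.0, "dx": 0.0, "dy": 0.0, "rotation": 0.0, "yaw": np.nan,
         "identity": np.arange(n)}
    )
    stim = StimulusSet(
        images=np.zeros((n, 4, 4), dtype=np.float32),
        class_labels=labels, partition_tags=tags, transform_meta=meta,
        stimulus_ids=[f"s{i}" for i in range(n)],
    )
    per_class_sel = {
        "face": np.arange(n_units) < n_informative,
        "a": np.zeros(n_units, dtype=bool),
        "b": np.zeros(n_units, dtype=bool),
    }
    return table, stim, per_class_sel


class TestLinearDetector:
    def test_separable_training_accuracy(self):
        x = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = [0, 0, 1, 1]
        clf = fit_linear_detector(x, y)
        assert np.all(clf.predict(x) == y)

    def test_duplicated_features_same_predictions(self):
        # well-separated classes: feature duplication cannot move any point
        # across the margin
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(-2, 0.3, (20, 3)), rng.normal(2, 0.3, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        a = fit_linear_detector(x, y).predict(x)
        b = fit_linear_detector(np.hstack([x, x]), y).predict(np.hstack([x, x]))
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_detector(np.zeros((5, 2)), [1, 1, 1, 1, 1])

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(50):
            x = rng.normal(size=(60, 5))
            y = rng.permutation([0] * 30 + [1] * 30)
            clf = fit_linear_detector(x[:40], y[:40])
            accs.append(np.mean(clf.predict(x[40:]) == y[40:]))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)


class TestDetectionExperiment:
    def test_planted_units_beat_shuffled_control(self):
        rng = np.random.default_rng(2)
        table, stim, sel = _feature_stimulus(rng)
        face = detection_experiment(
            table, stim, sel,
            DetectionConfig(unit_counts=(6,), n_trials=30, population="face_selective", seed=0),
        ).accuracy["accuracy"]
        shuf = detection_experiment(
            table, stim, sel,
            DetectionConfig(unit_counts=(6,), n_trials=100, population="shuffled_control", seed=0),
        ).accuracy["accuracy"]
        assert face.mean() > shuf.mean() + 3 * shuf.std()
        assert 0.4 <= shuf.mean() <= 0.6

    def test_full_population_zero_sampling_variance(self):
        rng = np.random.default_rng(3)
        table, stim, sel = _feature_stimulus(rng)
        res = detection_experiment(
            table, stim, sel,
            DetectionConfig(unit_counts=(6,), n_trials=5, population="face_selective", seed=1),
        )
        assert res.accuracy["accuracy"].std() == 0.0

    def test_oversized_count_rejected(self):
        rng = np.random.default_rng(4)
        table, stim, sel = _feature_stimulus(rng)
        with pytest.raises(ValueError, match="exceeds"):
            detection_experiment(
                table, stim, sel,
                DetectionConfig(unit_counts=(7,), population="face_selective"),
            )

    def test_double_dipping_guard(self):
        rng = np.random.default_rng(5)
        table, stim, sel = _feature_stimulus(rng)
        stim.stimulus_ids[0] = stim.stimulus_ids[-1]  # selection id reused in test
        with pytest.raises(ValueError, match="leak"):
            detection_experiment(table, stim, sel, DetectionConfig(unit_counts=(6,)))


class TestPopulations:
    def test_partition_disjoint_and_covering(self):
        per_class = {
            "face": np.array([1, 0, 1, 0, 0], dtype=bool),
            "a": np.array([0, 1, 1, 0, 0], dtype=bool),
        }
        pools = unit_populations(per_class, 5)
        face = set(pools["face_selective"])
        nonface = set(pools["non_face_selective"])
        none = set(pools["non_selective"])
        assert face | nonface | none == set(range(5))
        assert not face & nonface and not face & none and not nonface & none
        assert set(pools["all_selective"]) == face | nonface

    def test_ablation_runs_and_records_empty(self):
        rng = np.random.default_rng(6)
        table, stim, sel = _feature_stimulus(rng)
        sel = dict(sel)
        sel["a"] = np.zeros(table.n_units, dtype=bool)
        res = population_ablation(
            table, stim, sel,
            DetectionConfig(unit_counts=(6,), n_trials=5),
            populations=("face_selective", "non_face_selective"),
        )
        by_pop = dict(tuple(res.accuracy.groupby("population")))
        assert by_pop["non_face_selective"]["accuracy"].isna().all()
        assert by_pop["face_selective"]["accuracy"].notna().all()


class TestTransformTransfer:
    def _levels(self, rng, decay):
        table, stim, sel = _feature_stimulus(rng, signal=3.0)
        cols = np.flatnonzero(sel["face"])
        tables, labels = {}, {}
        test = np.asarray(stim.partition_tags) == "test"
        for lv, d in decay.items():
            v = table.values[test].copy()
            face = np.asarray(stim.class_labels)[test] == "face"
            v[np.ix_(face, cols)] -= 3.0 * (1 - d)  # signal shrinks with level
            tables[lv] = ResponseTable("conv5", v, table.unit_order, ["t"] * v.shape[0])
            labels[lv] = list(np.asarray(stim.class_labels)[test])
        return table, stim, cols, tables, labels

    def test_canonical_equals_direct_path(self):
        rng = np.random.default_rng(7)
        table, stim, cols, tables, labels = self._levels(rng, {0.0: 1.0})
        df = transform_transfer(table, stim, tables, labels, cols)
        train = np.asarray(stim.partition_tags) == "train"
        y = (np.asarray(stim.class_labels) == "face").astype(int)
        clf = fit_linear_detector(table.values[train][:, cols], y[train])
        test = np.asarray(stim.partition_tags) == "test"
        pred = clf.predict(table.values[test][:, cols])
        yt = y[test]
        direct = np.mean(
            [np.mean(pred[yt == c] == c) for c in (0, 1)]
        )
        assert df["accuracy"].iloc[0] == pytest.approx(direct)

    def test_degradation_with_level(self):
        rng = np.random.default_rng(8)
        table, stim, cols, tables, labels = self._levels(
            rng, {0.0: 1.0, 1.0: 0.1}
        )
        df = transform_transfer(table, stim, tables, labels, cols).set_index("level")
        assert df.loc[1.0, "accuracy"] <= df.loc[0.0, "accuracy"] + 0.05

    def test_empty_levels_rejected(self):
        rng = np.random.default_rng(9)
        table, stim, sel = _feature_stimulus(rng)
        with pytest.raises(ValueError):
            transform_transfer(table, stim, {}, {}, np.arange(3))
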