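"""Evaluation: grouped splits, metrics against brute-force oracles,
repeated holdout, grid search and the survival table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pearlrot.classify import TINY_CNN
from pearlrot.evaluate import (
    MetricsSummary,
    classification_metrics,
    grid_search,
    grouped_stratified_split,
    macro_f1_from_per_class,
    repeated_holdout,
    survival_summary,
)
from pearlrot.imaging import ImageDataset
from pearlrot.reference import GRAFT_SURVIVAL_ROWS, LOSSES_DURING_CULTIVATION
from pearlrot.simulate import CLASSES

from test_classify import _color_cohort, _sample  # reuse toy-sample builders


def _pearl_labels(n_per_class):
    labels = {}
    for cls, n in zip(CLASSES, n_per_class):
        for i in range(n):
            labels[f"{cls[:2]}{i:02d}"] = cls
    return labels


class TestGroupedStratifiedSplit:
    def test_twenty_pearls_split_14_3_3(self):
        labels = _pearl_labels((6, 6, 8))
        plan = grouped_stratified_split(labels, seed=0)
        sizes = {s: len(plan.pearls(s)) for s in ("train", "val", "test")}
        assert sizes == {"train": 14, "val": 3, "test": 3}

    def test_every_pearl_in_exactly_one_split(self):
        labels = _pearl_labels((5, 7, 9))
        plan = grouped_stratified_split(labels, seed=1)
        assert sorted(plan.assignment) == sorted(labels)
        assert set(plan.assignment.values()) <= {"train", "val", "test"}

    def test_class_proportions_within_one_pearl(self):
        labels = _pearl_labels((10, 12, 20))
        plan = grouped_stratified_split(labels, seed=2)
        for cls, n in zip(CLASSES, (10, 12, 20)):
            in_test = sum(
                1 for p, lab in labels.items() if lab == cls and plan.assignment[p] == "test"
            )
            assert abs(in_test - 0.15 * n) <= 1.0

    def test_seed_reproducibility_and_repeat_variation(self):
        labels = _pearl_labels((6, 6, 8))
        a = grouped_stratified_split(labels, seed=5, repeat_index=0)
        b = grouped_stratified_split(labels, seed=5, repeat_index=0)
        c = grouped_stratified_split(labels, seed=5, repeat_index=1)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment

    def test_test_membership_frequency_matches_fraction(self):
        labels = _pearl_labels((6, 6, 8))
        counts = {p: 0 for p in labels}
        n_rep = 100
        for r in range(n_rep):
            plan = grouped_stratified_split(labels, seed=11, repeat_index=r)
            for p in plan.pearls("test"):
                counts[p] += 1
        se = np.sqrt(0.15 * 0.85 / n_rep)
        for p, c in counts.items():
            assert abs(c / n_rep - 0.15) < 3 * se + 0.05  # apportionment granularity

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            grouped_stratified_split(_pearl_labels((3, 3, 3)), fractions=(0.5, 0.2, 0.2))


def _brute_force_metrics(y_true, y_pred):
    """Independent oracle: metrics straight from confusion counts."""
    out = {}
    f1s, supports = [], []
    for cls in CLASSES:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        f1s.append(f1)
        supports.append(sum(1 for t in y_true if t == cls))
        out[f"f1_{cls.lower()}"] = f1
    out["accuracy"] = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    out["macro_f1"] = sum(f1s) / len(f1s)
    out["weighted_f1"] = sum(f * s for f, s in zip(f1s, supports)) / sum(supports)
    return out


class TestClassificationMetrics:
    @given(st.lists(st.tuples(st.sampled_from(CLASSES), st.sampled_from(CLASSES)), min_size=1, max_size=60))
    def test_matches_brute_force_confusion_arithmetic(self, pairs):
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        got = classification_metrics(y_true, y_pred)
        want = _brute_force_metrics(y_true, y_pred)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-12)

    def test_perfect_predictions(self):
        y = ["Round", "Atypical", "Other"] * 4
        m = classification_metrics(y, list(y))
        assert all(m[k] == 1.0 for k in m)

    def test_known_confusion_counts_give_f1_0p8(self):
        # Round: TP=8, FP=2, FN=2 -> F1 = 16/20 = 0.8
        y_true = ["Round"] * 10 + ["Other"] * 2
        y_pred = ["Round"] * 8 + ["Other"] * 2 + ["Round"] * 2
        m = classification_metrics(y_true, y_pred)
        assert m["f1_round"] == pytest.approx(0.8)

    def test_weighted_equals_macro_for_equal_supports(self, rng):
        y_true = [c for c in CLASSES for _ in range(20)]
        y_pred = [CLASSES[i] for i in rng.integers(0, 3, size=60)]
        m = classification_metrics(y_true, y_pred)
        assert m["weighted_f1"] == pytest.approx(m["macro_f1"], abs=1e-12)

    def test_macro_from_per_class_is_plain_mean(self):
        assert macro_f1_from_per_class((0.826, 0.752, 0.852)) == pytest.approx(0.81, abs=0.0005)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])


class _PerfectModel:
    """Injectable oracle classifier: emits one-hot of the true labels."""

    backbone = TINY_CNN

    def predict_proba_samples(self, samples):
        probs = np.zeros((len(samples), 3))
        for i, s in enumerate(samples):
            probs[i, CLASSES.index(s.label)] = 1.0
        return probs


@pytest.fixture(scope="module")
def dataset():
    return ImageDataset(samples=_color_cohort(n_per_class=5, samples_per_pearl=2), variant="full")


class TestRepeatedHoldout:
    def test_perfect_classifier_gives_unit_metrics_zero_sd(self, dataset):
        summary = repeated_holdout(
            dataset,
            n_repeats=5,
            classifier_factory=lambda *a, **k: _PerfectModel(),
        )
        for level in ("sample", "pearl"):
            agg = summary.aggregate(level)
            assert agg["accuracy"] == (1.0, 0.0)
            assert agg["macro_f1"] == (1.0, 0.0)

    def test_single_repeat_reduces_to_one_split(self, dataset):
        summary = repeated_holdout(dataset, n_repeats=1, classifier_factory=lambda *a, **k: _PerfectModel())
        assert sorted(summary.df["level"]) == ["pearl", "sample"]

    def test_csv_column_order(self, dataset):
        summary = repeated_holdout(dataset, n_repeats=1, classifier_factory=lambda *a, **k: _PerfectModel())
        header = summary.to_csv().splitlines()[0]
        assert header == "repeat,level,accuracy,weighted_f1,macro_f1,f1_round,f1_atypical,f1_other"


class TestGridSearch:
    def test_singleton_grid_returns_that_configuration(self):
        train = _color_cohort(n_per_class=4, samples_per_pearl=1)
        val = _color_cohort(n_per_class=2, samples_per_pearl=1, seed=5)
        for v in val:  # distinct pearl ids from the training cohort
            v.pearl_id = "v" + v.pearl_id
        params, df = grid_search(train, val, {"lr": [1e-3], "epochs": [5]})
        assert params["lr"] == 1e-3 and params["epochs"] == 5
        assert len(df) == 1

    def test_degenerate_learning_rate_never_selected(self):
        train = _color_cohort(n_per_class=4, samples_per_pearl=1)
        val = _color_cohort(n_per_class=2, samples_per_pearl=1, seed=5)
        for v in val:
            v.pearl_id = "v" + v.pearl_id
        params, df = grid_search(train, val, {"lr": [1e-3, 200.0], "epochs": [10]})
        assert params["lr"] == 1e-3
        assert len(df) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], [], {"lr": []})


class TestSurvivalSummary:
    def test_reference_counts_reproduce_printed_percentages(self):
        table = survival_summary(GRAFT_SURVIVAL_ROWS, losses_during_cultivation=LOSSES_DURING_CULTIVATION)
        body = table[table["label"] != "Total"]
        assert list(body["pct_alive"]) == [60, 63, 20, 70, 0, 76]
        total = table[table["label"] == "Total"].iloc[0]
        assert total["n_grafted"] == 137 and total["n_remaining"] == 77
        assert total["n_monitored"] == 52

    def test_full_survival_is_100_percent(self):
        table = survival_summary([("x", 17, 17)])
        assert table.iloc[0]["pct_alive"] == 100

    @pytest.mark.parametrize("row", [("x", 5, 6), ("x", 0, 0), ("x", 5, -1)])
    def test_invalid_counts_rejected(self, row):
        with pytest.raises(ValueError):
            survival_summary([row])


def test_metrics_summary_aggregate_requires_rows():
    summary = MetricsSummary(df=pd.DataFrame({"level": [], "accuracy": []}))
    with pytest.raises(ValueError):
        summary.aggregate("pearl")
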