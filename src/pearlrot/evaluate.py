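"""Grouped repeated-holdout evaluation, metrics, grid search, survival table.

Evaluation is grouped by pearl: every sample of a pearl lands in the same
split, so a model never sees the test pearls during training.  Splits are
70/15/15 train/validation/test, stratified by class (largest-remainder
apportionment so the integer counts track the fractions as closely as
possible) with best-effort balanced representation of harvest-date groups,
and repeated with independent seeds (repeated holdout).

Metrics are reported at two levels: *sample* (each weekly/daily image
scored on its own) and *pearl* (majority vote over the pearl's samples).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score

from .classify import (
    DEFAULT_HYPERPARAMS,
    TINY_CNN,
    BackboneSpec,
    HeadSpec,
    TrainedModel,
    majority_vote,
    predict_proba,
    train_classifier,
)
from .imaging import ImageDataset, PearlSample
from .simulate import CLASSES

__all__ = [
    "SplitPlan",
    "MetricsSummary",
    "grouped_stratified_split",
    "classification_metrics",
    "macro_f1_from_per_class",
    "repeated_holdout",
    "grid_search",
    "survival_summary",
]

SPLITS = ("train", "val", "test")


@dataclass
class SplitPlan:
    """Pearl-level assignment for one holdout repeat."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    repeat_index: int
    seed: int

    def pearls(self, split: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def samples(self, dataset: ImageDataset, split: str) -> list[PearlSample]:
        return [s for s in dataset.samples if self.assignment[s.pearl_id] == split]


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n * f for f in fractions]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def grouped_stratified_split(
    dataset: ImageDataset | Mapping[str, str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    repeat_index: int = 0,
    harvest_groups: Mapping[str, str] | None = None,
) -> SplitPlan:
    """Randomise pearls (not samples) into train/val/test.

    Within each class, pearls are grouped by harvest-date group, shuffled
    within group, interleaved across groups (so each split receives a
    spread of harvest dates where group sizes permit) and apportioned by
    largest remainder.  Deterministic for a given (seed, repeat_index).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if isinstance(dataset, ImageDataset):
        label_of = dataset.labels_by_pearl()
    else:
        label_of = dict(dataset)
    harvest_groups = harvest_groups or {}
    rng = np.random.default_rng([seed, repeat_index])
    assignment: dict[str, str] = {}
    for cls in CLASSES:
        ids = sorted(p for p, lab in label_of.items() if lab == cls)
        if not ids:
            continue
        groups: dict[str, list[str]] = {}
        for p in ids:
            groups.setdefault(harvest_groups.get(p, "all"), []).append(p)
        shuffled = []
        for g in sorted(groups):
            member = list(groups[g])
            rng.shuffle(member)
            shuffled.append(member)
        rng.shuffle(shuffled)
        interleaved = [p for tup in itertools.zip_longest(*shuffled) for p in tup if p is not None]
        counts = _largest_remainder(len(interleaved), fractions)
        pos = 0
        for split, c in zip(SPLITS, counts):
            for p in interleaved[pos : pos + c]:
                assignment[p] = split
            pos += c
    return SplitPlan(assignment=assignment, fractions=tuple(fractions), repeat_index=repeat_index, seed=seed)


def classification_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    probabilities: np.ndarray | None = None,
) -> dict:
    """Accuracy, per-class F1, macro F1 and support-weighted F1.

    Per-class F1 is 0 when undefined (no true and no predicted samples of
    the class); macro F1 is their unweighted mean, weighted F1 the
    support-weighted mean.
    """
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("need equal-length non-empty label lists")
    labels = list(CLASSES)
    per_class = f1_score(y_true, y_pred, labels=labels, average=None, zero_division=0)
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "macro_f1": float(np.mean(per_class)),
        "weighted_f1": float(f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)),
    }
    for cls, f1 in zip(labels, per_class):
        out[f"f1_{cls.lower()}"] = float(f1)
    return out


def macro_f1_from_per_class(per_class_f1: Sequence[float]) -> float:
    """Macro-average F1: the unweighted mean of the per-class F1 scores."""
    scores = np.asarray(per_class_f1, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one per-class score")
    return float(scores.mean())


@dataclass
class MetricsSummary:
    """Per-repeat metric rows plus aggregation over repeats."""

    df: pd.DataFrame  # columns: repeat, level, accuracy, weighted_f1, macro_f1, f1_*, flagged

    def aggregate(self, level: str = "pearl") -> dict:
        """Mean and SD of each metric over repeats at the given level.

        Repeats flagged as degenerate (a class absent from the test split)
        are excluded from the per-class F1 aggregation but still count for
        accuracy and the averaged F1s.
        """
        sub = self.df[self.df["level"] == level]
        if sub.empty:
            raise ValueError(f"no rows at level {level!r}")
        out = {}
        for col in ("accuracy", "weighted_f1", "macro_f1"):
            out[col] = (float(sub[col].mean()), float(sub[col].std(ddof=0)))
        clean = sub[~sub["flagged"]]
        basis = clean if not clean.empty else sub
        for cls in CLASSES:
            col = f"f1_{cls.lower()}"
            out[col] = (float(basis[col].mean()), float(basis[col].std(ddof=0)))
        return out

    def to_csv(self) -> str:
        cols = ["repeat", "level", "accuracy", "weighted_f1", "macro_f1"] + [f"f1_{c.lower()}" for c in CLASSES]
        return self.df[cols].to_csv(index=False)


def repeated_holdout(
    dataset: ImageDataset,
    n_repeats: int = 100,
    head: HeadSpec = HeadSpec(),
    hyperparams: dict | None = None,
    backbone: BackboneSpec = TINY_CNN,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    harvest_groups: Mapping[str, str] | None = None,
    feature_cache: dict | None = None,
    classifier_factory: Callable[..., TrainedModel] | None = None,
) -> MetricsSummary:
    """Repeated grouped holdout: split, train, evaluate, aggregate.

    Each repeat draws an independent grouped stratified split, trains the
    head on the train split (validating on the validation split) and scores
    the test split at sample level and at pearl level (majority vote).
    ``classifier_factory`` replaces :func:`train_classifier` for testing.

    Backbone features are computed once per sample and shared across
    repeats (the backbone is frozen, so features are split-independent).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    trainer = classifier_factory or train_classifier
    cache = {} if feature_cache is None else feature_cache
    rows = []
    for r in range(n_repeats):
        plan = grouped_stratified_split(dataset, fractions, seed=seed, repeat_index=r, harvest_groups=harvest_groups)
        train = plan.samples(dataset, "train")
        val = plan.samples(dataset, "val")
        test = plan.samples(dataset, "test")
        if not train or not test:
            raise ValueError("degenerate split: empty train or test")
        hp = {**DEFAULT_HYPERPARAMS, **(hyperparams or {}), "seed": int(np.random.default_rng([seed, r, 1]).integers(2**31))}
        model = trainer(train, val, head=head, hyperparams=hp, backbone=backbone, feature_cache=cache)
        # sample level (stub models used in tests may provide their own
        # sample-wise probability method)
        prob_fn = getattr(model, "predict_proba_samples", None)
        y_true = [s.label for s in test]
        probs = prob_fn(test) if prob_fn is not None else predict_proba(model, test, feature_cache=cache)
        y_pred = [CLASSES[i] for i in probs.argmax(axis=1)]
        flagged = set(y_true) != set(CLASSES)
        rows.append({"repeat": r, "level": "sample", "flagged": flagged, **classification_metrics(y_true, y_pred)})
        # pearl level
        by_pearl: dict[str, list[int]] = {}
        for i, s in enumerate(test):
            by_pearl.setdefault(s.pearl_id, []).append(i)
        p_true = [test[idx[0]].label for idx in by_pearl.values()]
        p_pred = [majority_vote(probs[idx]) for idx in by_pearl.values()]
        flagged_p = set(p_true) != set(CLASSES)
        rows.append({"repeat": r, "level": "pearl", "flagged": flagged_p, **classification_metrics(p_true, p_pred)})
    return MetricsSummary(df=pd.DataFrame(rows))


def grid_search(
    train_samples: Sequence[PearlSample],
    val_samples: Sequence[PearlSample],
    grid: Mapping[str, Sequence],
    head: HeadSpec = HeadSpec(),
    backbone: BackboneSpec = TINY_CNN,
    feature_cache: dict | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search selected by validation accuracy.

    ``grid`` maps hyperparameter names to candidate values.  Ties are broken
    toward fewer epochs, then lower learning rate, then grid order.
    Returns the winning hyperparameter dict and the full results table.
    """
    keys = list(grid)
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
    if not combos:
        raise ValueError("empty grid")
    cache = {} if feature_cache is None else feature_cache
    rows = []
    for i, combo in enumerate(combos):
        hp = {**DEFAULT_HYPERPARAMS, **combo}
        model = train_classifier(train_samples, val_samples, head=head, hyperparams=hp, backbone=backbone, feature_cache=cache)
        val_acc = float(model.history["val_acc"].max())
        rows.append({"grid_index": i, **combo, "val_acc": val_acc})
    df = pd.DataFrame(rows)
    best = min(
        rows,
        key=lambda r: (
            -r["val_acc"],
            r.get("epochs", DEFAULT_HYPERPARAMS["epochs"]),
            r.get("lr", DEFAULT_HYPERPARAMS["lr"]),
            r["grid_index"],
        ),
    )
    params = {k: v for k, v in best.items() if k not in ("grid_index", "val_acc")}
    return params, df


def survival_summary(rows: Sequence[tuple], losses_during_cultivation: int | None = None) -> pd.DataFrame:
    """Graft-survival table: percent alive per group plus a totals row.

    ``rows`` are ``(label, n_grafted, n_remaining)`` triples (optionally
    ``(experiment, label, n_grafted, n_remaining)``).  Percent alive is
    ``100 * remaining / grafted`` truncated to an integer, matching how
    farm survival tables are conventionally printed.  When
    ``losses_during_cultivation`` is given, an ``n_monitored`` column on
    the totals row reports the oysters that actually entered the
    monitoring device.
    """
    parsed = []
    for row in rows:
        if len(row) == 4:
            exp, label, n, rem = row
        elif len(row) == 3:
            exp, (label, n, rem) = "", row
        else:
            raise ValueError("rows must be (label, grafted, remaining) or (experiment, label, grafted, remaining)")
        if n <= 0 or rem < 0:
            raise ValueError("counts must be non-negative (grafted > 0)")
        if rem > n:
            raise ValueError("remaining cannot exceed grafted")
        parsed.append({"experiment": exp, "label": label, "n_grafted": int(n), "n_remaining": int(rem)})
    if not parsed:
        raise ValueError("no rows")
    df = pd.DataFrame(parsed)
    df["pct_alive"] = (100 * df["n_remaining"] // df["n_grafted"]).astype(int)
    total_n = int(df["n_grafted"].sum())
    total_rem = int(df["n_remaining"].sum())
    total = {
        "experiment": "",
        "label": "Total",
        "n_grafted": total_n,
        "n_remaining": total_rem,
        "pct_alive": int(100 * total_rem // total_n) if total_n else 0,
    }
    if losses_during_cultivation is not None:
        df["n_monitored"] = pd.NA
        total["n_monitored"] = total_rem - int(losses_during_cultivation)
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
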