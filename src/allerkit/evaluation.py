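"""Evaluation framework: confusion metrics, stratified 10-fold CV, ROC/AUC,
parameter sweeps and predictor adapters for every engine.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/(TP+FP+TN+FN). Cross-validation is stratified so every fold holds a
nearly equal share of each class; the overall figure is the unweighted mean
of the fold metrics (pooled confusion counts are available as an option).
The similarity-based rules carry no trained state, but their allergen
reference is still restricted to the training folds — otherwise a held-out
allergen would match itself and sensitivity would be trivially perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .motifs import ElicitParams, MotifLibrary, elicit_motifs, motif_predict
from .records import Label, SequenceDataset, Verdict
from .rules import (
    Rule1Params,
    Rule2Params,
    WordIndex,
    build_word_index,
    rule1_predict,
    rule2_predict,
    rule_both_predict,
)
from .svm import SvmModel, SvmParams, svm_predict, svm_train


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallied with allergen as the positive class."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.TN + other.TN, self.FN + other.FN
        )

    @staticmethod
    def from_verdicts(ds: SequenceDataset, verdicts: Sequence[Verdict]) -> "ConfusionCounts":
        by_id = {v.query_id: v for v in verdicts}
        tp = fp = tn = fn = 0
        for rec in ds:
            if rec.label is Label.UNKNOWN:
                raise ValueError(f"record {rec.id!r} has no label; cannot score")
            pred = by_id[rec.id].is_allergen
            if rec.label is Label.ALLERGEN:
                tp, fn = tp + pred, fn + (not pred)
            else:
                fp, tn = fp + pred, tn + (not pred)
        return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity / specificity / accuracy (and optional AUC), as fractions.

    A ratio with zero denominator is ``None`` (missing), never 0.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    auc: float | None = None


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Derive the standard metrics from confusion counts."""
    if c.total == 0:
        raise ValueError("no evaluated records")
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    acc = (c.TP + c.TN) / c.total
    return MetricSet(sensitivity=sens, specificity=spec, accuracy=acc)


@dataclass
class FoldPlan:
    """K disjoint test-index sets covering the dataset, class-stratified."""

    folds: list[np.ndarray]
    seed: int

    def __len__(self) -> int:
        return len(self.folds)

    def split(self, i: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_indices, test_indices) for fold i over n records."""
        test = self.folds[i]
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        return np.nonzero(mask)[0], test


def make_folds(ds: SequenceDataset, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition; per-fold class counts differ by <= 1."""
    y = np.array([1 if rec.label is Label.ALLERGEN else 0 for rec in ds])
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(y)), y)]
    return FoldPlan(folds=folds, seed=seed)


class Predictor(Protocol):
    """A trainable (or reference-conditioned) classifier over datasets."""

    def fit(self, train: SequenceDataset) -> None: ...

    def predict(self, queries: SequenceDataset) -> list[Verdict]: ...


@dataclass
class CVResult:
    overall: MetricSet
    per_fold: list[MetricSet]
    fold_counts: list[ConfusionCounts]
    pooled: MetricSet


def _mean_metrics(per_fold: list[MetricSet]) -> MetricSet:
    def mean(values: list[float | None]) -> float | None:
        present = [v for v in values if v is not None]
        return float(np.mean(present)) if present else None

    return MetricSet(
        sensitivity=mean([m.sensitivity for m in per_fold]),
        specificity=mean([m.specificity for m in per_fold]),
        accuracy=mean([m.accuracy for m in per_fold]),
        auc=mean([m.auc for m in per_fold]),
    )


def cross_validate(
    ds: SequenceDataset,
    predictor_factory: Callable[[], Predictor],
    k: int = 10,
    seed: int = 0,
    folds: FoldPlan | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of a predictor factory.

    Each fold trains a fresh predictor on the other k-1 folds and scores the
    held-out fold; the overall MetricSet is the unweighted mean over folds
    (``pooled`` aggregates confusion counts first instead).
    """
    plan = folds if folds is not None else make_folds(ds, k=k, seed=seed)
    per_fold: list[MetricSet] = []
    fold_counts: list[ConfusionCounts] = []
    for i in range(len(plan)):
        train_idx, test_idx = plan.split(i, len(ds))
        train = ds.subset(train_idx)
        test = ds.subset(test_idx)
        predictor = predictor_factory()
        try:
            predictor.fit(train)
            verdicts = predictor.predict(test)
        except Exception as exc:
            raise RuntimeError(f"predictor failed on fold {i}: {exc}") from exc
        counts = ConfusionCounts.from_verdicts(test, verdicts)
        fold_counts.append(counts)
        per_fold.append(compute_metrics(counts))
    pooled = compute_metrics(sum(fold_counts, ConfusionCounts()))
    return CVResult(overall=_mean_metrics(per_fold), per_fold=per_fold, fold_counts=fold_counts, pooled=pooled)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and trapezoid AUC from scores (higher = more allergen-like).

    The threshold sweep walks the unique score values from high to low; ties
    are grouped into a single step, which makes the trapezoid AUC equal to
    the pairwise-concordance (Mann-Whitney) statistic with ties counted 1/2.
    Returns (points, auc) where points is an (m, 2) array of (FPR, TPR).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tied-score group
    distinct = np.nonzero(np.diff(sorted_scores, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# predictor adapters
# ---------------------------------------------------------------------------


def _training_allergens(train: SequenceDataset) -> SequenceDataset:
    allergens = train.filter_label(Label.ALLERGEN)
    if len(allergens) == 0:
        raise ValueError("training folds contain no allergens")
    return allergens


@dataclass
class Rule1Predictor:
    """Word-match rule conditioned on the training folds' allergens."""

    params: Rule1Params = field(default_factory=Rule1Params)
    index: WordIndex | None = None

    def fit(self, train: SequenceDataset) -> None:
        self.index = build_word_index(_training_allergens(train), self.params.wordsize)

    def predict(self, queries: SequenceDataset) -> list[Verdict]:
        assert self.index is not None, "fit before predict"
        return [rule1_predict(rec, self.index, self.params) for rec in queries]


@dataclass
class Rule2Predictor:
    """Sliding-window identity rule conditioned on training allergens."""

    params: Rule2Params = field(default_factory=Rule2Params)
    allergens: SequenceDataset | None = None

    def fit(self, train: SequenceDataset) -> None:
        self.allergens = _training_allergens(train)

    def predict(self, queries: SequenceDataset) -> list[Verdict]:
        assert self.allergens is not None, "fit before predict"
        return [rule2_predict(rec, self.allergens, self.params) for rec in queries]


@dataclass
class RuleBothPredictor:
    """Conjunction/disjunction of rule 1 and rule 2."""

    r1: Rule1Params = field(default_factory=Rule1Params)
    r2: Rule2Params = field(default_factory=Rule2Params)
    mode: str = "or"
    index: WordIndex | None = None
    allergens: SequenceDataset | None = None

    def fit(self, train: SequenceDataset) -> None:
        self.allergens = _training_allergens(train)
        self.index = build_word_index(self.allergens, self.r1.wordsize)

    def predict(self, queries: SequenceDataset) -> list[Verdict]:
        assert self.index is not None and self.allergens is not None
        return [
            rule_both_predict(rec, self.index, self.allergens, self.r1, self.r2, mode=self.mode)
            for rec in queries
        ]


@dataclass
class MotifPredictor:
    """Iterative (or single-shot) motif library trained on fold allergens."""

    params: ElicitParams = field(default_factory=ElicitParams)
    scan_evalue: float = 0.01
    iterative: bool = True
    library: MotifLibrary | None = None

    def fit(self, train: SequenceDataset) -> None:
        self.library = elicit_motifs(_training_allergens(train), self.params, iterative=self.iterative)

    def predict(self, queries: SequenceDataset) -> list[Verdict]:
        assert self.library is not None, "fit before predict"
        return motif_predict(self.library, queries, self.scan_evalue)


@dataclass
class SvmPredictor:
    """Composition SVM trained on both classes of the training folds."""

    params: SvmParams = field(default_factory=SvmParams)
    model: SvmModel | None = None

    def fit(self, train: SequenceDataset) -> None:
        self.model = svm_train(train, self.params)

    def predict(self, queries: SequenceDataset) -> list[Verdict]:
        assert self.model is not None, "fit before predict"
        return svm_predict(self.model, queries)


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Cross-validated metrics along one parameter grid (same folds throughout)."""

    parameter: str
    values: list
    metrics: list[MetricSet]
    counts: list[ConfusionCounts]


def sweep(
    ds: SequenceDataset,
    parameter: str,
    values: Sequence,
    factory_for_value: Callable[[object], Callable[[], Predictor]],
    k: int = 10,
    seed: int = 0,
) -> SweepResult:
    """Cross-validate a family of predictors over a parameter grid.

    The same fold plan (seeded once) is reused at every grid point so the
    resulting curves are comparable point by point.
    """
    if len(values) == 0:
        raise ValueError("parameter grid must be non-empty")
    plan = make_folds(ds, k=k, seed=seed)
    metrics: list[MetricSet] = []
    counts: list[ConfusionCounts] = []
    for value in values:
        result = cross_validate(ds, factory_for_value(value), folds=plan)
        metrics.append(result.overall)
        counts.append(sum(result.fold_counts, ConfusionCounts()))
    return SweepResult(parameter=parameter, values=list(values), metrics=metrics, counts=counts)
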