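"""Incremental feature selection (IFS) with a cross-validated classifier.

Nested prefixes F_k = {f_1 .. f_k} of the mRMR list are each evaluated by
stratified ten-fold cross-validation; confusion counts are pooled across the
held-out folds (micro-averaging), giving one SN/SP/ACC/MCC quadruple per
prefix length.  The optimal feature count is the smallest k attaining the
maximum MCC.  The default classifier mirrors an SMO-trained support vector
machine with default settings: linear kernel, complexity constant C = 1, and
features standardized to zero mean / unit variance on the training folds
only.  The classifier is pluggable through :class:`ClassifierSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.linear_model import LogisticRegression

from .enrichment import FeatureMatrix
from .metrics import ConfusionCounts, MetricSet, compute_metrics

__all__ = [
    "ClassifierSpec",
    "FoldAssignment",
    "IFSRecord",
    "IFSResult",
    "FittedModel",
    "stratified_folds",
    "cross_validate",
    "run_ifs",
    "train_final",
    "predict_unlabeled",
]

_CLASSIFIERS = {
    "svm-linear": lambda params: SVC(kernel="linear", C=1.0, **params),
    "linear-svc": lambda params: LinearSVC(C=1.0, **params),
    "logreg": lambda params: LogisticRegression(max_iter=1000, **params),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier + hyperparameters; must expose fit/predict."""

    name: str = "svm-linear"
    params: dict = field(default_factory=dict)
    standardize: bool = True

    def build(self) -> Pipeline:
        if self.name not in _CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.name!r}; options: {sorted(_CLASSIFIERS)}")
        clf = _CLASSIFIERS[self.name](dict(self.params))
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("clf", clf))
        return Pipeline(steps)


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold index; stratified so each fold's class counts are
    within one sample of an even split.  Reused identically across every
    prefix size of an IFS sweep."""

    fold_of: np.ndarray = field(repr=False)
    n_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass(frozen=True)
class IFSRecord:
    k: int
    metrics: MetricSet
    confusion: ConfusionCounts


@dataclass(frozen=True)
class IFSResult:
    records: tuple[IFSRecord, ...]
    optimal_k: int

    @property
    def optimal_record(self) -> IFSRecord:
        return next(r for r in self.records if r.k == self.optimal_k)

    def curve(self) -> list[dict]:
        """IFS curve rows (k, SN, SP, ACC, MCC) for export/plotting."""
        return [{"k": r.k, **r.metrics.rounded()} for r in self.records]


def stratified_folds(labels: np.ndarray, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified fold assignment.

    Within each class the sample indices are shuffled with the seed and dealt
    round-robin over the folds, so per-fold class counts differ by at most
    one.  Each class must have at least ``n_folds`` members.
    """
    labels = np.asarray(labels)
    rng = np.random.RandomState(seed)
    fold_of = np.empty(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples, fewer than {n_folds} folds"
            )
        idx = idx[rng.permutation(len(idx))]
        fold_of[idx] = np.arange(len(idx)) % n_folds
    return FoldAssignment(fold_of=fold_of, n_folds=n_folds, seed=seed)


def cross_validate(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    feature_subset: Sequence[int],
    clf: ClassifierSpec,
    folds: FoldAssignment,
) -> tuple[ConfusionCounts, MetricSet]:
    """Pooled-confusion cross-validation on a column subset of the matrix.

    Standardization parameters are fit on the training folds only (the
    pipeline refits per fold).  A training fold containing a single class is
    a hard error.
    """
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    X = matrix.scores[:, feature_subset]
    y = np.asarray(labels)
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold in range(folds.n_folds):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training split for fold {fold} contains a single class")
        model = clf.build()
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        truth = y[te]
        pooled = pooled + ConfusionCounts(
            tp=int(((pred == 1) & (truth == 1)).sum()),
            tn=int(((pred == 0) & (truth == 0)).sum()),
            fp=int(((pred == 1) & (truth == 0)).sum()),
            fn=int(((pred == 0) & (truth == 1)).sum()),
        )
    return pooled, compute_metrics(pooled)


def run_ifs(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    ranking,
    k_min: int = 5,
    k_max: int = 500,
    step: int = 1,
    clf: ClassifierSpec | None = None,
    folds: FoldAssignment | None = None,
    seed: int = 0,
) -> IFSResult:
    """Sweep prefix sizes k of the mRMR list (k_min..k_max inclusive).

    The same fold assignment is shared by every k, so the per-k metrics are
    comparable.  ``optimal_k`` is the smallest k attaining the maximum MCC.
    ``ranking`` is a RankedFeatures or a raw index sequence.
    """
    order = list(ranking.mrmr_order) if hasattr(ranking, "mrmr_order") else list(ranking)
    if k_min < 1 or k_max < k_min:
        raise ValueError(f"empty IFS range: k_min={k_min}, k_max={k_max}")
    if k_max > len(order):
        raise ValueError(f"k_max={k_max} exceeds the {len(order)} ranked features")
    clf = clf or ClassifierSpec()
    folds = folds or stratified_folds(labels, seed=seed)

    records = []
    for k in range(k_min, k_max + 1, step):
        confusion, metrics = cross_validate(matrix, labels, order[:k], clf, folds)
        records.append(IFSRecord(k=k, metrics=metrics, confusion=confusion))
    best = max(r.metrics.mcc for r in records)
    optimal_k = min(r.k for r in records if r.metrics.mcc == best)
    return IFSResult(records=tuple(records), optimal_k=optimal_k)


@dataclass
class FittedModel:
    """A trained pipeline plus everything needed to score new genes in the
    same feature space: the selected term ids (in order) and the classifier
    spec.  Standardization parameters live inside the fitted pipeline."""

    pipeline: Pipeline
    feature_ids: tuple[tuple[str, str], ...]  # (term_id, namespace) in model order
    spec: ClassifierSpec

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "FittedModel":
        model = joblib.load(path)
        if not isinstance(model, FittedModel):
            raise TypeError(f"{path} does not contain a FittedModel")
        return model


def train_final(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    feature_subset: Sequence[int],
    clf: ClassifierSpec | None = None,
) -> FittedModel:
    """Fit the final prediction model on all labeled samples using the
    selected feature columns (typically the IFS optimum)."""
    clf = clf or ClassifierSpec()
    feature_subset = list(feature_subset)
    pipeline = clf.build()
    pipeline.fit(matrix.scores[:, feature_subset], np.asarray(labels))
    return FittedModel(
        pipeline=pipeline,
        feature_ids=tuple(matrix.features[j] for j in feature_subset),
        spec=clf,
    )


def predict_unlabeled(model: FittedModel, matrix: FeatureMatrix):
    """Score unlabeled genes with a fitted model.

    Columns are matched to the model's features by (term_id, namespace), so
    the unlabeled matrix may carry extra columns but must contain every model
    feature.  Returns a DataFrame with gene, predicted label and decision
    value (signed distance to the separating hyperplane where available).
    """
    import pandas as pd

    col_of = {feat: j for j, feat in enumerate(matrix.features)}
    try:
        cols = [col_of[feat] for feat in model.feature_ids]
    except KeyError as exc:
        raise ValueError(f"unlabeled matrix is missing model feature {exc.args[0]!r}") from None
    X = matrix.scores[:, cols]
    if matrix.n_genes == 0:
        return pd.DataFrame(columns=["gene", "label", "decision_value"])
    pred = model.pipeline.predict(X)
    if hasattr(model.pipeline, "decision_function"):
        decision = model.pipeline.decision_function(X)
    else:  # pragma: no cover - all built-in classifiers expose it
        decision = model.pipeline.predict_proba(X)[:, 1]
    return pd.DataFrame(
        {"gene": list(matrix.genes), "label": pred.astype(int), "decision_value": decision}
    )
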