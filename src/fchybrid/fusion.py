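"""Feature fusion, the hybrid CNN-SVM classifier, cross-validation and metrics.

Per subject the classifier fuses a 37-vector: the 5 SRS subscale scores, 16
deep features from the static-FC branch and 16 from the dynamic-FC branch
(fixed slices 0:5, 5:21, 21:37).  Within every cross-validation fold both CNN
branches are retrained on that fold's training subjects only, feature columns
are z-scored with training-fold statistics, and a linear-kernel SVM is fitted
— no validation subject touches any training step.

Evaluation reports accuracy, sensitivity, specificity, false-positive and
false-negative rates, precision and F1 from the confusion counts, with ASD
(label 1) as the positive class.  Metrics with zero denominators are reported
as NaN rather than 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .feature_cnn import CnnBranchExtractor
from .io_core import (
    DimensionError,
    Phenotype,
    PipelineConfig,
    SubjectRecord,
    ValidationError,
)

__all__ = [
    "FEATURE_SLICES",
    "FeatureBundle",
    "ConfusionCounts",
    "MetricReport",
    "CvPlan",
    "CvResult",
    "HybridConnectomeClassifier",
    "make_cv_plan",
    "run_fold",
    "cross_validate",
    "compute_metrics",
    "confusion_from_labels",
    "fit_baselines",
    "subgroup_report",
]

FEATURE_SLICES = {
    "srs": slice(0, 5),
    "static": slice(5, 21),
    "dynamic": slice(21, 37),
}


@dataclass(frozen=True)
class FeatureBundle:
    """One subject's fused 37-vector (SRS, static-deep, dynamic-deep)."""

    subject_id: str
    vector: np.ndarray
    slices: dict = field(default_factory=lambda: dict(FEATURE_SLICES))

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float).reshape(-1)
        if vec.size != 37:
            raise DimensionError(f"feature bundle must have 37 entries, got {vec.size}")
        if not np.isfinite(vec).all():
            raise ValidationError(f"{self.subject_id}: non-finite feature entry")
        object.__setattr__(self, "vector", vec)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Classification metrics; NaN marks a metric with a zero denominator."""

    counts: ConfusionCounts
    acc: float
    sen: float
    spe: float
    fpr: float
    fnr: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc, "sen": self.sen, "spe": self.spe,
            "fpr": self.fpr, "fnr": self.fnr,
            "precision": self.precision, "f1": self.f1,
        }


def _ratio(num: int, denom: int) -> float:
    return num / denom if denom > 0 else math.nan


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Exact metric formulas from confusion counts (positive class = ASD)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sen = _ratio(tp, tp + fn)
    precision = _ratio(tp, tp + fp)
    if math.isnan(sen) or math.isnan(precision) or (precision + sen) == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * sen / (precision + sen)
    return MetricReport(
        counts=counts,
        acc=_ratio(tp + tn, counts.total),
        sen=sen,
        spe=_ratio(tn, tn + fp),
        fpr=_ratio(fp, fp + tn),
        fnr=_ratio(fn, fn + tp),
        precision=precision,
        f1=f1,
    )


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


# --------------------------------------------------------------------- CV plan
@dataclass(frozen=True)
class CvPlan:
    k: int
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train_ids, val_ids)
    stratified: bool
    seed: int


def make_cv_plan(phenotypes: Sequence[Phenotype], k: int, seed: int) -> CvPlan:
    """Stratified, seeded k-fold split over subject ids."""
    ids = np.array([p.subject_id for p in phenotypes])
    labels = np.array([p.label for p in phenotypes])
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} subjects; cannot make {k} stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(
        (tuple(ids[tr]), tuple(ids[va])) for tr, va in skf.split(ids, labels)
    )
    return CvPlan(k=k, folds=folds, stratified=True, seed=seed)


# ------------------------------------------------------------------ classifier
def _stack_records(records: Sequence[SubjectRecord]):
    srs = np.stack([r.phenotype.srs for r in records])
    static = np.stack([r.static_fc for r in records])
    dynamic = np.stack([np.moveaxis(r.dynamic_fc, -1, 0) for r in records])  # (n,Q,R,R)
    y = np.array([r.phenotype.label for r in records], dtype=int)
    return srs, static, dynamic, y


class HybridConnectomeClassifier(BaseEstimator, ClassifierMixin):
    """The full hybrid model: two CNN branches -> fused features -> linear SVM.

    ``fit`` takes a sequence of :class:`SubjectRecord` (labels are read from
    the phenotypes unless ``y`` is passed explicitly).  Feature columns are
    z-scored with the training statistics before the SVM.
    """

    def __init__(
        self,
        *,
        svm_C: float = 1.0,
        learning_rate: float = 1e-4,
        max_epochs: int = 50,
        batch_size: int = 8,
        dropout: float = 0.5,
        leaky_slope: float = 0.01,
        random_state: int = 0,
    ):
        self.svm_C = svm_C
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        self.random_state = random_state

    def _extractor(self, kind: str, seed: int) -> CnnBranchExtractor:
        return CnnBranchExtractor(
            kind=kind,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            dropout=self.dropout,
            leaky_slope=self.leaky_slope,
            random_state=seed,
        )

    def fit(self, records: Sequence[SubjectRecord], y: np.ndarray | None = None):
        records = list(records)
        srs, static, dynamic, labels = _stack_records(records)
        if y is not None:
            labels = np.asarray(y, dtype=int)
        classes, counts = np.unique(labels, return_counts=True)
        if classes.size < 2 or counts.min() < 2:
            raise ValidationError("need at least 2 subjects per class to fit")
        seeds = np.random.SeedSequence(self.random_state).generate_state(2) % (2**31)
        self.static_extractor_ = self._extractor("static", int(seeds[0])).fit(static, labels)
        self.dynamic_extractor_ = self._extractor("dynamic", int(seeds[1])).fit(dynamic, labels)
        features = self._raw_features(srs, static, dynamic)
        self.scaler_ = StandardScaler().fit(features)
        self.svm_ = SVC(kernel="linear", C=self.svm_C).fit(
            self.scaler_.transform(features), labels
        )
        self.classes_ = classes
        self.feature_slices_ = dict(FEATURE_SLICES)
        self.feature_means_ = features.mean(axis=0)  # Shapley baseline
        return self

    def _raw_features(self, srs, static, dynamic) -> np.ndarray:
        f_static = self.static_extractor_.transform(static)
        f_dynamic = self.dynamic_extractor_.transform(dynamic)
        return np.hstack([srs, f_static, f_dynamic])

    def features(self, records: Sequence[SubjectRecord]) -> np.ndarray:
        """Fused raw (unscaled) 37-d feature matrix for ``records``."""
        check_is_fitted(self, "svm_")
        srs, static, dynamic, _ = _stack_records(list(records))
        return self._raw_features(srs, static, dynamic)

    def feature_bundles(self, records: Sequence[SubjectRecord]) -> list[FeatureBundle]:
        feats = self.features(records)
        return [
            FeatureBundle(subject_id=r.subject_id, vector=v)
            for r, v in zip(records, feats)
        ]

    def decision_function(self, records: Sequence[SubjectRecord]) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(self.scaler_.transform(self.features(records)))

    def decision_from_raw(self, feature_matrix: np.ndarray) -> np.ndarray:
        """SVM decision values for raw (unscaled) 37-d feature rows."""
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(self.scaler_.transform(feature_matrix))

    def predict(self, records: Sequence[SubjectRecord]) -> np.ndarray:
        return (self.decision_function(records) > 0).astype(int)


# ------------------------------------------------------------ cross-validation
@dataclass
class FoldResult:
    fold: int
    report: MetricReport
    model: HybridConnectomeClassifier
    val_ids: tuple[str, ...]
    predictions: pd.DataFrame  # subject_id, label, prediction, decision_value


@dataclass
class CvResult:
    plan: CvPlan
    folds: list[FoldResult]
    mean: dict[str, float]
    best_fold: int

    @property
    def best_model(self) -> HybridConnectomeClassifier:
        return self.folds[self.best_fold].model

    def predictions(self) -> pd.DataFrame:
        frames = []
        for fr in self.folds:
            frame = fr.predictions.copy()
            frame["fold"] = fr.fold
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def run_fold(
    train_records: Sequence[SubjectRecord],
    val_records: Sequence[SubjectRecord],
    config: PipelineConfig,
    seed: int,
) -> tuple[MetricReport, HybridConnectomeClassifier, pd.DataFrame]:
    """Train on the fold's training records only and evaluate on its validation set."""
    model = HybridConnectomeClassifier(
        svm_C=config.svm_C,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        dropout=config.dropout,
        leaky_slope=config.leaky_slope,
        random_state=seed,
    ).fit(train_records)
    decision = model.decision_function(val_records)
    pred = (decision > 0).astype(int)
    y_val = np.array([r.phenotype.label for r in val_records], dtype=int)
    report = compute_metrics(confusion_from_labels(y_val, pred))
    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in val_records],
            "label": y_val,
            "prediction": pred,
            "decision_value": decision,
        }
    )
    return report, model, frame


def cross_validate(
    records: Sequence[SubjectRecord],
    config: PipelineConfig,
    seed: int,
    y: np.ndarray | None = None,
) -> CvResult:
    """Full k-fold CV with per-fold CNN retraining; keeps the best-ACC fold's model.

    ``y`` optionally overrides the labels carried by the records (used for
    permutation-null checks); the stratified plan always follows the labels in
    use.
    """
    records = list(records)
    by_id = {r.subject_id: r for r in records}
    if y is not None:
        y = np.asarray(y, dtype=int)
        records = [
            SubjectRecord(
                phenotype=Phenotype(
                    subject_id=r.subject_id,
                    label=int(lbl),
                    srs=r.phenotype.srs,
                    sex=r.phenotype.sex,
                    age=r.phenotype.age,
                    site=r.phenotype.site,
                ),
                static_fc=r.static_fc,
                dynamic_fc=r.dynamic_fc,
            )
            for r, lbl in zip(records, y)
        ]
        by_id = {r.subject_id: r for r in records}
    plan = make_cv_plan([r.phenotype for r in records], config.n_folds, seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(plan.k) % (2**31)
    folds: list[FoldResult] = []
    for i, (train_ids, val_ids) in enumerate(plan.folds):
        try:
            report, model, frame = run_fold(
                [by_id[s] for s in train_ids],
                [by_id[s] for s in val_ids],
                config,
                int(fold_seeds[i]),
            )
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed in fold {i}: {exc}") from exc
        folds.append(FoldResult(fold=i, report=report, model=model,
                                val_ids=val_ids, predictions=frame))
    mean = {
        key: float(np.mean([fr.report.as_dict()[key] for fr in folds]))
        for key in folds[0].report.as_dict()
    }
    accs = [fr.report.acc for fr in folds]
    best_fold = int(np.argmax(accs))  # argmax takes the lowest index on ties
    return CvResult(plan=plan, folds=folds, mean=mean, best_fold=best_fold)


# -------------------------------------------------------------------- baselines
def fit_baselines(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> dict[str, MetricReport]:
    """SVM / MLP / RF / LR on identical fused features (z-scored with train stats).

    MLP: hidden layers (64, 16).  RF: 100 trees.  LR: threshold 0.5 on the
    positive-class probability, ties classified positive.
    """
    scaler = StandardScaler().fit(train_features)
    xtr = scaler.transform(train_features)
    xva = scaler.transform(val_features)
    ytr = np.asarray(train_labels, dtype=int)
    yva = np.asarray(val_labels, dtype=int)
    models = {
        "svm": SVC(kernel="linear", C=config.svm_C),
        "mlp": MLPClassifier(hidden_layer_sizes=(64, 16), max_iter=1000,
                             random_state=seed),
        "rf": RandomForestClassifier(n_estimators=100, random_state=seed),
        "lr": LogisticRegression(max_iter=1000, random_state=seed),
    }
    out: dict[str, MetricReport] = {}
    for name, model in models.items():
        model.fit(xtr, ytr)
        if name == "lr":
            pred = (model.predict_proba(xva)[:, 1] >= 0.5).astype(int)
        else:
            pred = np.asarray(model.predict(xva), dtype=int)
        out[name] = compute_metrics(confusion_from_labels(yva, pred))
    return out


# -------------------------------------------------------------- subgroup report
_AGE_BIN_WIDTH = 10.0  # decades


def subgroup_report(
    predictions: pd.DataFrame,
    phenotypes: Sequence[Phenotype],
    by: str,
) -> dict[str, MetricReport]:
    """Recompute metrics within strata of sex, decade age bins, or site."""
    if by not in ("sex", "age", "site"):
        raise ValidationError(f"unknown grouping key {by!r}; use sex, age or site")
    meta = {p.subject_id: p for p in phenotypes}
    missing = [s for s in predictions["subject_id"] if s not in meta]
    if missing:
        raise ValidationError(f"predictions reference unknown subject(s) {missing[:5]}")

    def stratum(pheno: Phenotype) -> str:
        value = getattr(pheno, by)
        if value is None:
            raise ValidationError(f"{pheno.subject_id}: missing {by} metadata")
        if by == "age":
            lo = int(value // _AGE_BIN_WIDTH * _AGE_BIN_WIDTH)
            return f"{lo}-{lo + int(_AGE_BIN_WIDTH)}"
        return str(value)

    groups: dict[str, list[int]] = {}
    for idx, sid in enumerate(predictions["subject_id"]):
        groups.setdefault(stratum(meta[sid]), []).append(idx)
    out: dict[str, MetricReport] = {}
    for name in sorted(groups):
        rows = predictions.iloc[groups[name]]
        out[name] = compute_metrics(
            confusion_from_labels(rows["label"].to_numpy(), rows["prediction"].to_numpy())
        )
    return out
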