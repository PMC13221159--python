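"""Nested cross-validation, the metric suite, and the paired bootstrap.

Evaluation follows the double (nested) cross-validation design: a
stratified 10-fold outer loop estimates generalization; within each outer
training set a stratified 5-fold inner loop selects hyperparameters by
mean ROC-AUC.  All preprocessing (keyword screening, PCA, orthogonalization,
standardization) is refit on the training rows of every split — outer and
inner — so no fold statistic ever sees its own evaluation rows.

Repeated evaluation reruns the whole procedure under many seeds; paired
per-seed metric differences between two feature settings are summarized by
a percentile bootstrap confidence interval (2.5th/97.5th percentiles).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, ExtraTreesClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .blocks import BlockSet, FeatureBlock
from .fusion import FeaturePipeline

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVConfig",
    "EvaluationReport",
    "BootstrapResult",
    "f1_score",
    "accuracy",
    "roc_auc",
    "confusion_rates",
    "build_classifier",
    "default_model_grid",
    "double_cv",
    "repeated_cv",
    "summarize_repeats",
    "bootstrap_ci_diff",
]

METRIC_NAMES = ("f1", "accuracy", "roc_auc", "tpr", "fpr", "fnr", "tnr")


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts; positive class = high stress."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FP + FN), in percent.

    Undefined (no positive predictions and no positive truths) is
    reported as NaN, never silently 0.
    """
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        logger.warning("F1 undefined: no positives predicted or present")
        return math.nan
    return 100.0 * 2 * c.tp / denom


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total, in percent."""
    if c.total == 0:
        raise ValueError("accuracy undefined on an empty evaluation set")
    return 100.0 * (c.tp + c.tn) / c.total


def confusion_rates(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(TPR, FPR, FNR, TNR) in percent; TPR+FNR = FPR+TNR = 100."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("confusion rates undefined with an empty class")
    tpr = 100.0 * c.tp / (c.tp + c.fn)
    fpr = 100.0 * c.fp / (c.tn + c.fp)
    return tpr, fpr, 100.0 - tpr, 100.0 - fpr


def roc_auc(scores, labels) -> float:
    """ROC area in percent: P(random positive outscores random negative),
    ties counted half."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC-AUC undefined with a single class")
    return 100.0 * float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class MetricSet:
    """One evaluated fold's metric suite, all in percent."""

    f1: float
    accuracy: float
    roc_auc: float
    tpr: float
    fpr: float
    fnr: float
    tnr: float

    @classmethod
    def from_fold(cls, c: ConfusionCounts, scores, labels) -> "MetricSet":
        tpr, fpr, fnr, tnr = confusion_rates(c)
        return cls(f1_score(c), accuracy(c), roc_auc(scores, labels), tpr, fpr, fnr, tnr)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


# ---------------------------------------------------------------------------
# Classifier grid

_SVM_C_GRID = (0.01, 0.1, 1.0, 10.0)  # least complex (strongest regularization) first


def default_model_grid(model: str = "svm-linear") -> dict[str, list[dict]]:
    """Default hyperparameter candidates per classifier, ordered so the
    least complex setting comes first (the inner-CV tie-break)."""
    grids: dict[str, list[dict]] = {
        "svm-linear": [{"C": c} for c in _SVM_C_GRID],
        "svm-rbf": [{"C": c} for c in _SVM_C_GRID],
        "svm-sigmoid": [{"C": c} for c in _SVM_C_GRID],
        "svm-poly": [{"C": c, "degree": d} for c, d in product(_SVM_C_GRID, (2, 3))],
        "knn": [{"n_neighbors": k} for k in (3, 5, 7, 11)],
        "random-forest": [{"n_estimators": n} for n in (100, 300)],
        "extratrees": [{"n_estimators": n} for n in (100, 300)],
        "adaboost": [{"n_estimators": n} for n in (50, 100)],
    }
    if model not in grids:
        raise ValueError(f"unsupported model {model!r}; known: {sorted(grids)}")
    return {model: grids[model]}


def build_classifier(name: str, hyperparameters: dict | None = None, random_state: int = 0):
    """Instantiate a supported classifier exposing fit + decision scores."""
    params = dict(hyperparameters or {})
    try:
        if name == "svm-linear":
            return SVC(kernel="linear", **params)
        if name == "svm-rbf":
            return SVC(kernel="rbf", gamma="scale", **params)
        if name == "svm-sigmoid":
            return SVC(kernel="sigmoid", gamma="scale", **params)
        if name == "svm-poly":
            return SVC(kernel="poly", gamma="scale", **params)
        if name == "knn":
            return KNeighborsClassifier(**params)
        if name == "random-forest":
            return RandomForestClassifier(random_state=random_state, **params)
        if name == "extratrees":
            return ExtraTreesClassifier(random_state=random_state, **params)
        if name == "adaboost":
            return AdaBoostClassifier(random_state=random_state, **params)
    except TypeError as exc:
        raise ValueError(f"invalid hyperparameters for {name!r}: {params}") from exc
    raise ValueError(f"unsupported model {name!r}")


def decision_scores(model, X) -> np.ndarray:
    """Continuous scores for ROC-AUC: decision_function when available,
    else positive-class probability."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclass
class CVConfig:
    """Nested-CV layout: 10 outer folds, 5 inner folds, stratified."""

    outer_k: int = 10
    inner_k: int = 5
    stratified: bool = True
    seed: int = 0
    model_grid: dict[str, list[dict]] | None = None
    tie_break: str = "least-complex-first"

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("outer_k and inner_k must both be >= 2")
        if self.model_grid is not None and not self.model_grid:
            raise ValueError("model grid must be nonempty")

    def grid(self) -> list[tuple[str, dict]]:
        grid = self.model_grid if self.model_grid is not None else default_model_grid()
        return [(name, params) for name, settings in grid.items() for params in settings]


@dataclass
class EvaluationReport:
    """Per-fold metrics plus mean (population SD) per metric."""

    feature_setting: str
    fold_metrics: list[MetricSet]
    fold_confusions: list[ConfusionCounts]
    selected: list[tuple[str, dict]]
    degenerate_folds: list[bool]
    seed: int
    n: int

    @property
    def outer_k(self) -> int:
        return len(self.fold_metrics)

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.fold_metrics])

    def mean(self, name: str) -> float:
        vals = self.metric_values(name)
        finite = vals[np.isfinite(vals)]
        if finite.size < vals.size:
            logger.info(
                "%s: %d fold(s) with undefined %s excluded from the mean",
                self.feature_setting, vals.size - finite.size, name,
            )
        return float(finite.mean()) if finite.size else math.nan

    def sd(self, name: str) -> float:
        vals = self.metric_values(name)
        finite = vals[np.isfinite(vals)]
        return float(finite.std(ddof=0)) if finite.size else math.nan

    def summary(self) -> dict[str, dict[str, float]]:
        return {name: {"mean": self.mean(name), "sd": self.sd(name)} for name in METRIC_NAMES}

    def to_dict(self) -> dict:
        return {
            "feature_setting": self.feature_setting,
            "seed": self.seed,
            "n": self.n,
            "fold_metrics": [m.as_dict() for m in self.fold_metrics],
            "fold_confusions": [
                {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn} for c in self.fold_confusions
            ],
            "selected": [{"model": m, "params": p} for m, p in self.selected],
            "degenerate_folds": list(self.degenerate_folds),
            "summary": self.summary(),
        }


def _as_blockset(features) -> BlockSet:
    if isinstance(features, BlockSet):
        return features
    if isinstance(features, FeatureBlock):
        return BlockSet(features, None)
    raise TypeError("features must be a FeatureBlock or BlockSet")


def _splitter(k: int, stratified: bool, seed: int):
    cls = StratifiedKFold if stratified else KFold
    return cls(n_splits=k, shuffle=True, random_state=seed)


def _select_hyperparameters(
    blocks: BlockSet, y: np.ndarray, train_idx: np.ndarray, cfg: CVConfig,
    pipeline: FeaturePipeline, inner_seed: int,
) -> tuple[str, dict]:
    """Inner-CV selection by mean ROC-AUC; preprocessing refit per inner
    split; ties go to the earliest (least complex) grid entry."""
    candidates = cfg.grid()
    inner = _splitter(cfg.inner_k, cfg.stratified, inner_seed)
    y_tr = y[train_idx]
    mean_auc = np.zeros(len(candidates))
    n_folds = 0
    for fit_rel, val_rel in inner.split(np.zeros(len(train_idx)), y_tr):
        fit_idx, val_idx = train_idx[fit_rel], train_idx[val_rel]
        fitted = pipeline.fit(blocks, fit_idx)
        X_fit = fitted.transform(blocks, fit_idx)
        X_val = fitted.transform(blocks, val_idx)
        if len(set(y[val_idx].tolist())) < 2:
            continue
        n_folds += 1
        for j, (name, params) in enumerate(candidates):
            model = build_classifier(name, params, random_state=inner_seed)
            model.fit(X_fit, y[fit_idx])
            mean_auc[j] += roc_auc(decision_scores(model, X_val), y[val_idx])
    if n_folds == 0:
        raise ValueError("no valid inner validation fold contained both classes")
    best = int(np.argmax(mean_auc > mean_auc.max() - 1e-9))
    return candidates[best]


def double_cv(
    features, labels, cfg: CVConfig, preprocessing: FeaturePipeline | None = None
) -> EvaluationReport:
    """Nested CV: outer folds estimate generalization, inner folds select
    hyperparameters, preprocessing is fitted on training rows only.

    ``features`` is a :class:`FeatureBlock` (used as-is, standardized) or a
    :class:`BlockSet` processed by ``preprocessing`` (a
    :class:`~lasap.fusion.FeaturePipeline`).
    """
    blocks = _as_blockset(features)
    y = np.asarray(labels, dtype=int)
    n = blocks.n_participants
    if len(y) != n:
        raise ValueError("labels do not match participant count")
    if n < cfg.outer_k:
        raise ValueError("fewer participants than outer folds")
    pipeline = preprocessing or FeaturePipeline(
        setting="linguistic" if blocks.acoustic is None else "combined_ortho",
        screen="off",
        variance_fraction=1.0,
    )

    fold_metrics, fold_confusions, selected, degenerate = [], [], [], []
    outer = _splitter(cfg.outer_k, cfg.stratified, cfg.seed)
    for fold_idx, (train_idx, test_idx) in enumerate(outer.split(np.zeros(n), y)):
        if len(set(y[train_idx].tolist())) < 2:
            raise ValueError(f"outer fold {fold_idx}: training rows contain one class")
        try:
            inner_seed = (cfg.seed * 1009 + fold_idx + 1) % (2**31 - 1)
            name, params = _select_hyperparameters(blocks, y, train_idx, cfg, pipeline, inner_seed)
            fitted = pipeline.fit(blocks, train_idx)
            X_train = fitted.transform(blocks, train_idx)
            X_test = fitted.transform(blocks, test_idx)
        except Exception as exc:
            raise RuntimeError(f"preprocessing failed in outer fold {fold_idx}: {exc}") from exc
        model = build_classifier(name, params, random_state=inner_seed)
        model.fit(X_train, y[train_idx])
        preds = np.asarray(model.predict(X_test), dtype=int)
        scores = decision_scores(model, X_test)
        counts = ConfusionCounts.from_predictions(y[test_idx], preds)
        fold_metrics.append(MetricSet.from_fold(counts, scores, y[test_idx]))
        fold_confusions.append(counts)
        selected.append((name, params))
        is_degenerate = len(set(preds.tolist())) < 2
        if is_degenerate:
            logger.info("outer fold %d predicted a single class", fold_idx)
        degenerate.append(is_degenerate)
    return EvaluationReport(
        feature_setting=pipeline.setting,
        fold_metrics=fold_metrics,
        fold_confusions=fold_confusions,
        selected=selected,
        degenerate_folds=degenerate,
        seed=cfg.seed,
        n=n,
    )


def repeated_cv(
    features, labels, cfg: CVConfig, n_repeats: int = 100,
    preprocessing: FeaturePipeline | None = None,
) -> list[EvaluationReport]:
    """Rerun double CV under ``n_repeats`` seeds (base seed + repeat index)."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    reports = []
    for r in range(n_repeats):
        rcfg = CVConfig(
            outer_k=cfg.outer_k, inner_k=cfg.inner_k, stratified=cfg.stratified,
            seed=cfg.seed + r, model_grid=cfg.model_grid, tie_break=cfg.tie_break,
        )
        reports.append(double_cv(features, labels, rcfg, preprocessing))
    return reports


def summarize_repeats(reports: list[EvaluationReport]) -> dict[str, dict[str, float]]:
    """Mean and population SD, over repeats, of the per-repeat mean metrics."""
    out = {}
    for name in METRIC_NAMES:
        means = np.array([rep.mean(name) for rep in reports])
        finite = means[np.isfinite(means)]
        out[name] = {
            "mean": float(finite.mean()) if finite.size else math.nan,
            "sd": float(finite.std(ddof=0)) if finite.size else math.nan,
        }
    return out


@dataclass
class BootstrapResult:
    """Percentile CI of per-seed paired metric differences (with - without)."""

    differences: dict[str, np.ndarray]
    lower: dict[str, float]
    upper: dict[str, float]
    lower_pct: float = 2.5
    upper_pct: float = 97.5

    def improvement_established(self, metric: str) -> bool:
        """True when the lower percentile bound exceeds zero."""
        return self.lower[metric] > 0.0

    def to_dict(self) -> dict:
        return {
            "lower_pct": self.lower_pct,
            "upper_pct": self.upper_pct,
            "metrics": {
                m: {
                    "lower": self.lower[m],
                    "upper": self.upper[m],
                    "improvement_established": self.improvement_established(m),
                    "differences": self.differences[m].tolist(),
                }
                for m in self.differences
            },
        }


def bootstrap_ci_diff(
    reports_with: list[EvaluationReport],
    reports_without: list[EvaluationReport],
    lower_pct: float = 2.5,
    upper_pct: float = 97.5,
    metrics: tuple[str, ...] = ("f1", "accuracy", "roc_auc"),
) -> BootstrapResult:
    """Percentile CI of the paired per-seed differences between two settings.

    Repeat ``i`` of both lists must share a seed (identical fold
    assignments) so each difference is paired.  Percentiles use linear
    interpolation between order statistics.
    """
    if len(reports_with) != len(reports_without):
        raise ValueError("paired report lists differ in length")
    for a, b in zip(reports_with, reports_without):
        if a.seed != b.seed:
            raise ValueError(f"unpaired seeds: {a.seed} vs {b.seed}")
    diffs, lower, upper = {}, {}, {}
    for m in metrics:
        d = np.array([a.mean(m) - b.mean(m) for a, b in zip(reports_with, reports_without)])
        diffs[m] = d
        lower[m] = float(np.percentile(d, lower_pct))
        upper[m] = float(np.percentile(d, upper_pct))
    return BootstrapResult(diffs, lower, upper, lower_pct, upper_pct)
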