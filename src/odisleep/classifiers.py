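"""Cutoff and SVM screening classifiers for OSA severity.

Two screening tasks are supported: ``severe`` (positive = AHI >= 30) and
``mod_severe`` (positive = AHI >= 15), plus the four-class severity
problem. Three model families:

* fixed single-index cutoffs (score >= cutoff is positive; the published
  clinic-derived cutoffs ship as defaults),
* ROC-optimised cutoffs maximising Youden's J = sensitivity +
  specificity - 1 over midpoints between adjacent unique scores,
* kernel SVMs on standardised features with stratified tenfold
  cross-validation and inner-fold grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ODI_FEATURES",
    "DEFAULT_CUTOFFS",
    "CutoffRule",
    "CutoffResult",
    "SVMSpec",
    "PredictionSet",
    "cutoff_predict",
    "optimize_cutoff",
    "svm_crossval",
    "svm_multiclass",
]

ODI_FEATURES = ("odi2", "odi3", "odi4t", "odi4a")

#: Published single-index cutoffs (events/h) by (task, dataset), where
#: ``all`` is the full cohort and ``tst_ge_4h`` the TST>=4h sub-cohort.
DEFAULT_CUTOFFS: dict[tuple[str, str], dict[str, float]] = {
    ("severe", "all"): {"odi2": 27.2, "odi3": 18.4, "odi4t": 11.2, "odi4a": 13.7},
    ("severe", "tst_ge_4h"): {"odi2": 27.2, "odi3": 18.4, "odi4t": 10.4, "odi4a": 13.7},
    ("mod_severe", "all"): {"odi2": 21.2, "odi3": 9.5, "odi4t": 7.3, "odi4a": 8.5},
    ("mod_severe", "tst_ge_4h"): {"odi2": 21.2, "odi3": 9.5, "odi4t": 7.3, "odi4a": 7.3},
}


@dataclass(frozen=True)
class CutoffRule:
    """Threshold rule on one oximetry index; score >= cutoff is positive."""

    feature: str
    cutoff: float
    task: str = "severe"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class PredictionSet:
    """Pooled per-patient predictions for one task."""

    frame: pd.DataFrame  # columns: patient_id, true, pred, score, fold
    task: str

    def __post_init__(self) -> None:
        required = {"patient_id", "true", "pred", "score", "fold"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"prediction frame missing columns {sorted(missing)}")
        if self.frame["patient_id"].duplicated().any():
            raise ValueError("every patient must appear exactly once")

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.frame["true"] == self.frame["pred"]).mean()


def cutoff_predict(
    values: pd.Series, labels: Sequence, rule: CutoffRule
) -> PredictionSet:
    """Classify each patient by comparing one index against the cutoff."""
    values = pd.Series(values)
    missing = values.index[values.isna()].tolist()
    if missing:
        raise ValueError(f"feature {rule.feature!r} missing for patients {missing}")
    frame = pd.DataFrame(
        {
            "patient_id": values.index,
            "true": np.asarray(labels),
            "pred": (values.to_numpy() >= rule.cutoff).astype(int),
            "score": values.to_numpy(dtype=float),
            "fold": -1,
        }
    )
    return PredictionSet(frame=frame, task=rule.task)


@dataclass(frozen=True)
class CutoffResult:
    """An ROC-optimised cutoff and its operating point."""

    rule: CutoffRule
    youden_j: float
    sensitivity_pct: float
    specificity_pct: float


def optimize_cutoff(
    scores: Sequence[float], labels: Sequence[int], *, feature: str = "score",
    task: str = "severe",
) -> CutoffResult:
    """Cutoff maximising Youden's J over midpoints of adjacent unique scores.

    Ties in J are broken toward the higher-specificity (higher) cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to optimise a cutoff")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("all scores identical; the feature is non-discriminative")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    best = None
    for c in candidates:
        pred = s >= c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        # candidates ascend, so >= keeps the higher (more specific) cutoff on ties
        if best is None or j >= best[0] - 1e-12:
            if best is None or j > best[0] + 1e-12 or spec >= best[3]:
                best = (j, c, sens, spec)
    j, c, sens, spec = best
    return CutoffResult(
        rule=CutoffRule(feature=feature, cutoff=float(c), task=task),
        youden_j=float(j),
        sensitivity_pct=100.0 * sens,
        specificity_pct=100.0 * spec,
    )


@dataclass(frozen=True)
class SVMSpec:
    """Configuration of the cross-validated SVM screening model."""

    features: tuple[str, ...] = ("odi2", "odi4a")
    kernel: str = "rbf"  # linear | polynomial2 | rbf
    C: float | None = None
    gamma: float | None = None
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    cv_folds: int = 10
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("features must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.kernel not in ("linear", "polynomial2", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def _make_svc(spec: SVMSpec, C: float, gamma: float) -> SVC:
    kw: dict = {"C": C}
    if spec.kernel == "linear":
        kw["kernel"] = "linear"
    elif spec.kernel == "polynomial2":
        kw.update(kernel="poly", degree=2, gamma=gamma)
    else:
        kw.update(kernel="rbf", gamma=gamma)
    return SVC(**kw)


def _fit_fold(spec: SVMSpec, X_tr: np.ndarray, y_tr: np.ndarray) -> Pipeline:
    """Standardise by the training fold and pick hyperparameters on it only."""
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", _make_svc(spec, C=1.0, gamma=0.1))]
    )
    grid: dict[str, list] = {}
    if spec.C is None:
        grid["svc__C"] = list(spec.C_grid)
    else:
        pipe.set_params(svc__C=spec.C)
    if spec.kernel != "linear":
        if spec.gamma is None:
            grid["svc__gamma"] = list(spec.gamma_grid)
        else:
            pipe.set_params(svc__gamma=spec.gamma)
    if grid:
        inner = StratifiedKFold(
            n_splits=spec.inner_folds, shuffle=True, random_state=spec.seed
        )
        search = GridSearchCV(pipe, grid, cv=inner, scoring="accuracy", n_jobs=1)
        search.fit(X_tr, y_tr)
        return search.best_estimator_
    pipe.fit(X_tr, y_tr)
    return pipe


def _crossval(
    X: pd.DataFrame, y: Sequence, spec: SVMSpec, task: str
) -> PredictionSet:
    Xv = X[list(spec.features)].to_numpy(dtype=float)
    yv = np.asarray(y)
    ids = X.index.to_numpy()
    classes, counts = np.unique(yv, return_counts=True)
    if counts.min() < spec.cv_folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has only {counts.min()} patients; "
            f"use fewer than {spec.cv_folds} folds"
        )
    outer = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    rows = []
    for fold, (tr, te) in enumerate(outer.split(Xv, yv)):
        model = _fit_fold(spec, Xv[tr], yv[tr])
        pred = model.predict(Xv[te])
        dec = model.decision_function(Xv[te])
        score = dec if dec.ndim == 1 else dec.max(axis=1)
        rows.append(
            pd.DataFrame(
                {"patient_id": ids[te], "true": yv[te], "pred": pred,
                 "score": score, "fold": fold}
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    return PredictionSet(frame=frame, task=task)


def svm_crossval(X: pd.DataFrame, y: Sequence[int], spec: SVMSpec,
                 *, task: str = "severe") -> PredictionSet:
    """Binary screening SVM evaluated by stratified k-fold CV.

    Features are standardised within each training fold; hyperparameters
    come from a grid search on the training fold only; out-of-fold
    predictions are pooled. Deterministic under a fixed ``spec.seed``.
    """
    return _crossval(X, y, spec, task)


def svm_multiclass(X: pd.DataFrame, y: Sequence[str], spec: SVMSpec,
                   *, task: str = "fourclass") -> PredictionSet:
    """Four-band severity SVM (one-vs-one voting), same CV protocol."""
    if len(set(y)) < 3:
        raise ValueError("multiclass task needs at least 3 classes present")
    return _crossval(X, y, spec, task)
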