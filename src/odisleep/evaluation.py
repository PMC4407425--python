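"""Diagnostic-validation statistics.

Everything needed to evaluate an oximetry screening model against the PSG
reference: multiclass confusion matrices with per-class sensitivities,
ROC curves with trapezoidal AUC (identical to the Mann-Whitney concordance
probability with half credit for ties), Bland-Altman limits of agreement,
OLS calibration of AHI on ODI features, Pearson chi-square tests on
contingency tables, and one-way ANOVA with post-hoc pairwise comparisons
computed from group summaries (n, mean, SD) alone — printed cohort tables
are enough, no raw data needed.

Post-hoc default is Games-Howell: severity groups of desaturation indices
are grossly heteroscedastic (the severe group's SD can be an order of
magnitude above the normal group's), and a pooled-variance procedure such
as Scheffé then has no power for comparisons among the mild groups.
Scheffé remains available via ``method="scheffe"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ROCCurve",
    "BlandAltmanResult",
    "GroupSummary",
    "CalibrationResult",
    "ChiSquareResult",
    "AnovaResult",
    "confusion_metrics",
    "roc_auc",
    "bland_altman",
    "linear_calibrate",
    "chi_square_test",
    "anova_from_summary",
    "posthoc_orderings",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i][j] = patients of true class i predicted as class j."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError("counts must be square and match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_predictions(cls, pred_set, labels: Sequence[str | int]) -> "ConfusionMatrix":
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(pred_set.frame["true"], pred_set.frame["pred"]):
            counts[index[t], index[p]] += 1
        return cls(labels=tuple(str(l) for l in labels), counts=counts)


@dataclass
class MetricsReport:
    """Accuracy / per-class sensitivity surface of a confusion matrix."""

    overall_accuracy_pct: float
    sensitivity_pct: dict[str, float]
    specificity_pct: float | None  # binary tasks only
    misclassification_pct: dict[tuple[str, str], float]
    auc: float | None = None


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Overall accuracy, per-class sensitivities, and cell-wise
    misclassification rates (each as % of the true class)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = cm.row_sums()
    acc = 100.0 * np.trace(cm.counts) / cm.total
    sens: dict[str, float] = {}
    mis: dict[tuple[str, str], float] = {}
    for i, lab in enumerate(cm.labels):
        if rows[i] == 0:
            sens[lab] = float("nan")
            continue
        sens[lab] = 100.0 * cm.counts[i, i] / rows[i]
        for j, plab in enumerate(cm.labels):
            if j != i:
                mis[(lab, plab)] = 100.0 * cm.counts[i, j] / rows[i]
    spec = None
    if len(cm.labels) == 2:
        # convention: first label is the negative class
        spec = sens[cm.labels[0]]
    return MetricsReport(
        overall_accuracy_pct=float(acc),
        sensitivity_pct=sens,
        specificity_pct=spec,
        misclassification_pct=mis,
    )


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve over all unique thresholds; AUC by trapezoidal integration.

    With ties given half credit this equals the Mann-Whitney concordance
    probability P(score_pos > score_neg) + 0.5 P(equal).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thr = roc_curve(y, s)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=float(np.trapezoid(tpr, fpr)))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between a reference and an estimate: bias and 95% limits."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def bland_altman(reference: Sequence[float], estimate: Sequence[float]) -> BlandAltmanResult:
    """Bias (mean of reference - estimate) and limits bias +/- 1.96 SD,
    with the sample (n-1) SD of the differences."""
    r = np.asarray(reference, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if r.size != e.size:
        raise ValueError("reference and estimate must have equal length")
    if r.size < 3:
        raise ValueError("need at least 3 paired values")
    d = r - e
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


@dataclass
class CalibrationResult:
    """OLS fit of the reference index on one or more oximetry features."""

    coefficients: dict[str, float]
    intercept: float
    r_squared: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept)
        for name, beta in self.coefficients.items():
            out = out + beta * X[name].to_numpy(dtype=float)
        return out


def linear_calibrate(predictors: pd.DataFrame, response: Sequence[float]) -> CalibrationResult:
    """Ordinary least squares with intercept; rejects collinear predictors."""
    import statsmodels.api as sm

    X = pd.DataFrame(predictors)
    y = np.asarray(response, dtype=float)
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more observations than predictors plus intercept")
    design = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        for j, col in enumerate(X.columns):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                raise ValueError(
                    f"predictor {col!r} is collinear with the other predictors"
                )
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    return CalibrationResult(
        coefficients={c: float(b) for c, b in zip(X.columns, fit.params[1:])},
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_test(table: Sequence[Sequence[int]]) -> ChiSquareResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = stats.chi2_contingency(t, correction=False)
    return ChiSquareResult(statistic=float(res[0]), df=int(res[2]),
                           p_value=float(res[1]))


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, sd) of one variable in one group; sd is the sample SD."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def anova_from_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, sd).

    Between-group SS comes from the group means about the grand mean;
    within-group SS from the (n-1)-weighted sample variances — identical to
    the raw-data F when the summaries used sample SDs.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    sd = np.array([g.sd for g in groups], dtype=float)
    N, k = n.sum(), len(groups)
    grand = (n * m).sum() / N
    ssb = (n * (m - grand) ** 2).sum()
    ssw = ((n - 1) * sd**2).sum()
    df_b, df_w = k - 1, int(N - k)
    if ssw == 0:
        f = 0.0 if ssb == 0 else float("inf")
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(f_statistic=float(f), df_between=df_b, df_within=df_w, p_value=p)


def _pair_p_games_howell(gi: GroupSummary, gj: GroupSummary, k: int) -> float:
    vi, vj = gi.sd**2 / gi.n, gj.sd**2 / gj.n
    se = np.sqrt(vi + vj)
    if se == 0:
        return 1.0 if gi.mean == gj.mean else 0.0
    t = abs(gi.mean - gj.mean) / se
    df = (vi + vj) ** 2 / (vi**2 / (gi.n - 1) + vj**2 / (gj.n - 1))
    return float(stats.studentized_range.sf(t * np.sqrt(2.0), k, df))


def _pair_p_scheffe(gi: GroupSummary, gj: GroupSummary, k: int,
                    msw: float, df_w: int) -> float:
    se2 = msw * (1.0 / gi.n + 1.0 / gj.n)
    if se2 == 0:
        return 1.0 if gi.mean == gj.mean else 0.0
    f = (gi.mean - gj.mean) ** 2 / se2 / (k - 1)
    return float(stats.f.sf(f, k - 1, df_w))


def posthoc_orderings(
    groups: Sequence[GroupSummary],
    alpha: float = 0.05,
    method: Literal["games-howell", "scheffe"] = "games-howell",
) -> list[tuple[int, int]]:
    """Significant pairwise mean orderings from group summaries.

    Returns 1-based index pairs ``(i, j)`` with mean_i < mean_j and an
    adjusted pairwise p below ``alpha``, the conventional "(i) < (j)"
    reading of post-hoc tables.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    msw = df_w = None
    if method == "scheffe":
        n = np.array([g.n for g in groups], dtype=float)
        sd = np.array([g.sd for g in groups], dtype=float)
        df_w = int(n.sum() - k)
        msw = float(((n - 1) * sd**2).sum() / df_w)
    pairs: list[tuple[int, int]] = []
    for a in range(k):
        for b in range(a + 1, k):
            if method == "games-howell":
                p = _pair_p_games_howell(groups[a], groups[b], k)
            elif method == "scheffe":
                p = _pair_p_scheffe(groups[a], groups[b], k, msw, df_w)
            else:
                raise ValueError(f"unknown post-hoc method {method!r}")
            if p < alpha:
                lo, hi = (a, b) if groups[a].mean < groups[b].mean else (b, a)
                pairs.append((lo + 1, hi + 1))
    return sorted(pairs)


def format_orderings(pairs: Sequence[tuple[int, int]]) -> str:
    """Render pairs as the conventional "(i) < (j)" string."""
    return "; ".join(f"({i}) < ({j})" for i, j in pairs)
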