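"""Diagnostic-accuracy statistics.

Confusion-matrix metrics with likelihood ratios, ROC curves with trapezoidal
AUC, Youden-optimal thresholds, percentile bootstrap confidence intervals
computed by threshold averaging (metrics are read at a fixed threshold on
each bootstrap ROC rather than at a fixed false-positive rate), single-gene
threshold classifiers, ensemble evaluation, and the Mann-Whitney U test for
group differences in expression.

Conventions: infection (PJI) is the positive class; a patient is classified
positive when the score (expression value or ensemble probability) is at or
above the threshold, since elevated expression indicates infection. Undefined
likelihood ratios at the boundary (specificity 0 or 1, sensitivity 0) are
reported as ``inf``/``0`` sentinels so that summaries always serialize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .expression import PJI, CohortTable


class MetricError(ValueError):
    """Metrics undefined for the given inputs (e.g. single-class truth)."""


class DegenerateCurveWarning(UserWarning):
    """ROC built from constant scores; AUC fixed at 0.5."""


METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy", "lr_pos", "lr_neg")


@dataclass
class DiagnosticSummary:
    """Point estimates (and optionally 95% CIs) of diagnostic accuracy.

    lr_pos = sens / (1 - spec); lr_neg = (1 - sens) / spec; boundary cases
    are inf/0 sentinels. ci_95 maps metric name -> (low, high).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    lr_pos: float
    lr_neg: float
    n_pos: int
    n_neg: int
    ci_95: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d["n_pos"], d["n_neg"] = self.n_pos, self.n_neg
        if self.ci_95:
            d["ci_95"] = {k: list(v) for k, v in self.ci_95.items()}
        return d


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return num / den


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray) -> DiagnosticSummary:
    """Diagnostic summary from binary predictions against binary truth."""
    predicted = np.asarray(predicted).astype(bool).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if predicted.shape != truth.shape:
        raise MetricError("predicted and truth must have equal length")
    if truth.all() or not truth.any():
        raise MetricError("truth contains a single class; metrics undefined")
    tp = int(np.sum(predicted & truth))
    fn = int(np.sum(~predicted & truth))
    tn = int(np.sum(~predicted & ~truth))
    fp = int(np.sum(predicted & ~truth))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(tp, tp + fp) if (tp + fp) else float("nan"),
        npv=_ratio(tn, tn + fn) if (tn + fn) else float("nan"),
        accuracy=(tp + tn) / len(truth),
        lr_pos=_ratio(sens, 1 - spec),
        lr_neg=_ratio(1 - sens, spec),
        n_pos=tp + fn,
        n_neg=tn + fp,
    )


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

@dataclass
class RocCurve:
    """ROC over all distinct score thresholds (descending) plus endpoints.

    Classification rule: positive iff score >= threshold; tied scores are
    grouped at a single threshold. auc is the trapezoidal area.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, truth: np.ndarray) -> RocCurve:
    """Build an ROC curve; constant scores yield a degenerate diagonal
    (AUC 0.5) with a :class:`DegenerateCurveWarning`."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if truth.all() or not truth.any():
        raise MetricError("truth contains a single class")
    if np.unique(scores).size == 1:
        warnings.warn("constant scores: degenerate ROC, AUC = 0.5",
                      DegenerateCurveWarning, stacklevel=2)
        thr = np.array([np.inf, scores[0]])
        return RocCurve(thr, np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5)
    fpr, tpr, thr = _skm.roc_curve(truth, scores, drop_intermediate=False)
    return RocCurve(thr, tpr, fpr, float(_skm.auc(fpr, tpr)))


def youden_threshold(roc: RocCurve) -> float:
    """Threshold maximizing Youden's J = TPR - FPR.

    Ties are broken toward higher specificity (lower FPR), then the higher
    threshold. When a finite threshold separates the classes with a gap, the
    midpoint of the gap between that score and the next lower score is
    returned. A fully degenerate curve (J maximal only at the
    classify-all-negative endpoint) returns ``inf`` with a warning.
    """
    j = roc.tpr - roc.fpr
    order = np.lexsort((-roc.thresholds, roc.fpr, -j))  # best J, low FPR, high thr
    best = order[0]
    thr = roc.thresholds[best]
    if not np.isfinite(thr):
        if j[best] <= 0:
            warnings.warn("no threshold improves on classify-all-negative",
                          DegenerateCurveWarning, stacklevel=2)
        return float("inf")
    finite = roc.thresholds[np.isfinite(roc.thresholds)]
    lower = finite[finite < thr]
    return float((thr + lower.max()) / 2) if lower.size else float(thr)


# --------------------------------------------------------------------------
# Bootstrap confidence intervals (threshold averaging)
# --------------------------------------------------------------------------

def _metric_at_threshold(scores, truth, threshold, metric):
    predicted = scores >= threshold
    if metric == "auc":
        return roc_curve(scores, truth).auc
    summary = confusion_metrics(predicted, truth)
    return getattr(summary, metric)


def bootstrap_threshold_average_ci(
    scores: np.ndarray,
    truth: np.ndarray,
    metric: str = "sensitivity",
    B: int = 2000,
    seed: int = 0,
    threshold: float | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap 95% CI for a metric at a fixed threshold.

    B stratified resamples (positives and negatives resampled separately, so
    no resample is single-class); on each, the ROC operating point at the
    *same* threshold is evaluated — averaging curves vertically at fixed
    thresholds — and the 2.5/97.5 percentiles across resamples form the CI.
    ``threshold`` defaults to the Youden threshold of the full data.
    ``metric`` may be any of ``sensitivity, specificity, ppv, npv, accuracy,
    lr_pos, lr_neg, auc``. Returns ``(point, ci_low, ci_high)``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if metric not in METRIC_NAMES + ("auc",):
        raise ValueError(f"unknown metric {metric!r}")
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if threshold is None:
        threshold = youden_threshold(roc_curve(scores, truth))
    point = _metric_at_threshold(scores, truth, threshold, metric)
    pos = np.flatnonzero(truth)
    neg = np.flatnonzero(~truth)
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        vals[b] = _metric_at_threshold(scores[idx], truth[idx], threshold, metric)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return float(point), float("nan"), float("nan")
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def _with_cis(scores, truth, threshold, B, seed) -> DiagnosticSummary:
    summary = confusion_metrics(scores >= threshold, truth)
    for i, m in enumerate(METRIC_NAMES):
        _, lo, hi = bootstrap_threshold_average_ci(
            scores, truth, metric=m, B=B, seed=seed + i, threshold=threshold
        )
        summary.ci_95[m] = (lo, hi)
    return summary


# --------------------------------------------------------------------------
# Cohort-level evaluation
# --------------------------------------------------------------------------

def evaluate_single_gene(
    cohort: CohortTable,
    gene: str,
    threshold: float | None = None,
    B: int = 2000,
    seed: int = 0,
) -> tuple[DiagnosticSummary, float]:
    """Single-gene threshold classifier: infection iff expression >= threshold.

    With ``threshold`` omitted the Youden-optimal threshold on the cohort is
    used. Returns the bootstrap-CI'd summary and the threshold applied.
    """
    sub = cohort.complete_cases([gene])
    if len(sub.patients) == 0:
        raise MetricError(f"no non-missing values for {gene}")
    scores = sub.values[gene].to_numpy()
    truth = sub.y().astype(bool)
    if threshold is None:
        threshold = youden_threshold(roc_curve(scores, truth))
    return _with_cis(scores, truth, threshold, B, seed), float(threshold)


def evaluate_ensemble(
    model,
    cohort: CohortTable,
    B: int = 2000,
    seed: int = 0,
) -> DiagnosticSummary:
    """Evaluate a trained ensemble on a labeled cohort.

    Classifies every complete-case patient with the ensemble (mean member
    probability, threshold 0.5) and returns the pooled summary with bootstrap
    CIs. Per-member summaries and their metric-wise mean (the averaged
    NN1-NN5 reading) are attached as ``per_member`` and ``member_mean``
    attributes: averaging per-member point estimates and pooling the ensemble
    probabilities answer slightly different questions, so both are reported.
    """
    from .ensemble import member_probabilities  # local import: avoids cycle

    sub = cohort.complete_cases(model.genes)
    truth = sub.y().astype(bool)
    probs = member_probabilities(model, sub)  # patients x members
    mean_prob = probs.mean(axis=1)
    summary = _with_cis(mean_prob, truth, 0.5, B, seed)

    per_member = [confusion_metrics(probs[:, m] >= 0.5, truth) for m in range(probs.shape[1])]
    member_mean = {
        name: float(np.mean([getattr(s, name) for s in per_member]))
        for name in METRIC_NAMES
    }
    summary.per_member = per_member
    summary.member_mean = member_mean
    return summary


# --------------------------------------------------------------------------
# Group-difference testing
# --------------------------------------------------------------------------

def group_test(cohort: CohortTable, gene: str) -> float:
    """Two-sided Mann-Whitney U P value for PJI vs non-PJI expression.

    Uses the exact U distribution when the combined sample size is at most 12
    and there are no ties, and the normal approximation with tie correction
    otherwise. Completely tied data give P = 1.
    """
    col = cohort.values[gene]
    x = col[cohort.labels == PJI].dropna().to_numpy()
    y = col[cohort.labels != PJI].dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise MetricError(f"empty group for {gene}")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(pooled) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
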