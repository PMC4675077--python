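"""Diagnostic evaluation: confusion metrics, likelihood ratios, ROC, Mood's test.

IBS is the positive class throughout; PV_IBS is the positive predictive
value.  AUC uses the Mann-Whitney rank formulation with ties credited
1/2, which is exactly the trapezoidal area under the stepped ROC curve.
Mood's median test dichotomizes at the pooled grand median ("above" vs
"not above") and uses the 1-df chi-square statistic without continuity
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

GROUPS = ("IBS", "HLT")


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    pv_ibs: float | None  # None when tp+fp == 0 (undefined, not 0)
    lr_pos: float  # math.inf when specificity == 1
    lr_neg: float  # math.nan when specificity == 0
    mean_confidence: float | None = None
    mean_confidence_correct: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["lr_pos"]):
            d["lr_pos"] = "inf"
        if isinstance(d["lr_neg"], float) and math.isnan(d["lr_neg"]):
            d["lr_neg"] = "undefined"
        return d


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """LR+ = sens/(1-spec); LR- = (1-sens)/spec.

    Returns ``math.inf`` for LR+ at perfect specificity and ``math.nan``
    for LR- at zero specificity.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    lr_pos = math.inf if specificity == 1.0 else sensitivity / (1.0 - specificity)
    lr_neg = math.nan if specificity == 0.0 else (1.0 - sensitivity) / specificity
    return lr_pos, lr_neg


def confusion_counts(true_groups, assigned_groups) -> tuple[int, int, int, int]:
    t = np.asarray(true_groups)
    a = np.asarray(assigned_groups)
    if t.shape != a.shape:
        raise ValueError("true and assigned label vectors differ in length")
    bad = sorted((set(t.tolist()) | set(a.tolist())) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown labels {bad}; allowed: {GROUPS}")
    tp = int(np.sum((t == "IBS") & (a == "IBS")))
    fn = int(np.sum((t == "IBS") & (a == "HLT")))
    tn = int(np.sum((t == "HLT") & (a == "HLT")))
    fp = int(np.sum((t == "HLT") & (a == "IBS")))
    return tp, fp, tn, fn


def report_from_counts(
    tp: int, fp: int, tn: int, fn: int,
    mean_confidence: float | None = None,
    mean_confidence_correct: float | None = None,
) -> EvalReport:
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    lr_pos, lr_neg = likelihood_ratios(sens, spec) if not (
        math.isnan(sens) or math.isnan(spec)
    ) else (math.nan, math.nan)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        accuracy=(tp + tn) / total,
        pv_ibs=(tp / (tp + fp)) if tp + fp else None,
        lr_pos=lr_pos, lr_neg=lr_neg,
        mean_confidence=mean_confidence,
        mean_confidence_correct=mean_confidence_correct,
    )


def confusion_metrics(true_groups, assigned_groups, confidences=None) -> EvalReport:
    """Confusion matrix and derived diagnostics for a labelled cohort.

    When per-sample confidences are supplied, the mean over all samples
    and the mean over correctly assigned samples are both reported.
    """
    tp, fp, tn, fn = confusion_counts(true_groups, assigned_groups)
    mean_conf = mean_conf_correct = None
    if confidences is not None:
        c = np.asarray(confidences, dtype=float)
        if c.shape[0] != len(true_groups):
            raise ValueError("confidences length mismatch")
        correct = np.asarray(true_groups) == np.asarray(assigned_groups)
        mean_conf = float(c.mean())
        mean_conf_correct = float(c[correct].mean()) if correct.any() else None
    return report_from_counts(tp, fp, tn, fn, mean_conf, mean_conf_correct)


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def auc_mann_whitney(scores, true_groups) -> float:
    """AUC as the Mann-Whitney U statistic over n_IBS * n_HLT, ties 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true_groups) == "IBS"
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(scores, true_groups) -> ROCCurve:
    """Threshold sweep over the unique score values, from (0,0) to (1,1)."""
    s = np.asarray(scores, dtype=float)
    y = (np.asarray(true_groups) == "IBS").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=auc_mann_whitney(s, true_groups))


def moods_median_test(values_a, values_b) -> tuple[float, float]:
    """Mood's median test: chi-square (1 df, no continuity correction) on
    the 2x2 table of counts above vs not-above the pooled grand median.

    Degenerate pooled samples (all values on one side of the grand
    median) give statistic 0 and p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    try:
        res = stats.median_test(a, b, ties="below", correction=False)
    except ValueError:
        warnings.warn("degenerate pooled sample in Mood's median test; p = 1")
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)
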