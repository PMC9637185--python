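"""Diagnostic performance of dichotomized multiclass labels.

A multiclass labeling is collapsed to a binary test at a chosen boundary
(positive = class >= threshold label), compared against a binary truth
(e.g. a clinical protein status), and summarized as a 2x2 table with the
standard statistics: sensitivity, specificity, prevalence, predictive
values and accuracy. Confidence intervals are exact Clopper-Pearson for
the binomial proportions and logit-based for the predictive values,
matching common diagnostic-calculator practice. Predictive values can
also be recomputed at an assumed population prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta, norm

__all__ = [
    "ConfusionTable",
    "DiagnosticReport",
    "dichotomize",
    "confusion",
    "clopper_pearson",
    "test_performance",
    "predictive_values_at_prevalence",
]


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class Estimate:
    """A proportion with its 95% confidence interval (NaN when undefined)."""

    value: float
    ci_low: float
    ci_high: float
    note: str = ""


@dataclass(frozen=True)
class DiagnosticReport:
    sensitivity: Estimate
    specificity: Estimate
    prevalence: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate


def dichotomize(labels, threshold_label: int) -> np.ndarray:
    """Binary vector: positive iff class label >= threshold_label."""
    return np.asarray(labels) >= threshold_label


def confusion(pred, truth) -> ConfusionTable:
    """2x2 counts from matched binary prediction and truth vectors."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionTable(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles; (0, .) at x=0, (., 1) at x=n."""
    if n <= 0:
        raise ValueError("n must be positive")
    alpha = 1.0 - conf
    lo = beta.ppf(alpha / 2, x, n - x + 1) if x > 0 else 0.0
    hi = beta.ppf(1 - alpha / 2, x + 1, n - x) if x < n else 1.0
    return float(lo), float(hi)


def _logit_ci(p: float, se_logit: float, conf: float = 0.95) -> tuple[float, float]:
    if p <= 0 or p >= 1 or not math.isfinite(se_logit):
        return (math.nan, math.nan)
    z = norm.ppf(0.5 + conf / 2)
    lo = math.log(p / (1 - p)) - z * se_logit
    hi = math.log(p / (1 - p)) + z * se_logit
    return (1 / (1 + math.exp(-lo)), 1 / (1 + math.exp(-hi)))


def _cp_estimate(x: int, n: int) -> Estimate:
    lo, hi = clopper_pearson(x, n)
    return Estimate(value=x / n, ci_low=lo, ci_high=hi)


def test_performance(t: ConfusionTable) -> DiagnosticReport:
    """Point estimates and 95% CIs for the six standard 2x2 statistics.

    Sensitivity, specificity, prevalence and accuracy carry exact
    Clopper-Pearson intervals; PPV/NPV carry standard logit intervals.
    A predictive value with a zero denominator is reported as NaN with a
    note (e.g. PPV when no positives were called).
    """
    if t.tp + t.fn < 1 or t.fp + t.tn < 1:
        raise ValueError("need at least one truth-positive and one truth-negative")
    n = t.n
    se = _cp_estimate(t.tp, t.tp + t.fn)
    sp = _cp_estimate(t.tn, t.tn + t.fp)
    prev = _cp_estimate(t.tp + t.fn, n)
    acc = _cp_estimate(t.tp + t.tn, n)

    def pv(num: int, den: int, name: str) -> Estimate:
        if den == 0:
            return Estimate(math.nan, math.nan, math.nan, note=f"{name} undefined: no calls")
        p = num / den
        if 0 < p < 1:
            se_logit = math.sqrt(1 / num + 1 / (den - num))
            lo, hi = _logit_ci(p, se_logit)
        else:  # boundary proportion: logit CI degenerate, report point only
            lo, hi = (math.nan, math.nan)
        return Estimate(value=p, ci_low=lo, ci_high=hi)

    return DiagnosticReport(
        sensitivity=se,
        specificity=sp,
        prevalence=prev,
        ppv=pv(t.tp, t.tp + t.fp, "PPV"),
        npv=pv(t.tn, t.tn + t.fn, "NPV"),
        accuracy=acc,
    )


def predictive_values_at_prevalence(se: float, sp: float, p: float) -> tuple[float, float]:
    """PPV and NPV at an assumed disease prevalence p (Bayes' rule).

    ppv = se*p / (se*p + (1-sp)(1-p));
    npv = sp(1-p) / ((1-se)p + sp(1-p)).
    Degenerate denominators yield NaN.
    """
    for name, v in (("se", se), ("sp", sp), ("p", p)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    d_ppv = se * p + (1 - sp) * (1 - p)
    d_npv = (1 - se) * p + sp * (1 - p)
    ppv = se * p / d_ppv if d_ppv > 0 else math.nan
    npv = sp * (1 - p) / d_npv if d_npv > 0 else math.nan
    return ppv, npv
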