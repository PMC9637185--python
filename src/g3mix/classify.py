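"""Three consecutive classification rules: proba, cutoff, stringent cutoff.

*proba* assigns each value to the class with maximal posterior probability
under the fitted mixture (fitted weights as priors). *cutoff* parses the
real line at the minimal-misclassification point between each pair of
adjacent classes — the root of the equal-weight density equality
phi(x; mu_L, sd_L) = phi(x; mu_R, sd_R) lying between the two means.
*s.cutoff* (stringent) widens the class-0 interval to the tolerable-error
endpoints of the two class-0-adjacent boundaries, reassigning borderline
values to the reference-like class.

Boundary naming follows the field convention: the boundary separating
class k-1 from class k (k >= 1) is "up-k"; its mirror below class 0 is
"down-k".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .mixture import Component, MixtureModel

__all__ = [
    "Boundary",
    "CutoffSet",
    "pairwise_cutoff",
    "cutoff_interval",
    "build_cutoffs",
    "classify_proba",
    "classify_cutoff",
    "classify_scutoff",
    "summarize",
    "heatmap_matrix",
]

log = logging.getLogger(__name__)

DEFAULT_R_TOL = 0.10


@dataclass(frozen=True)
class Boundary:
    """Cutoff between two adjacent classes.

    ``cstar`` is the minimal-misclassification point; ``interval`` is the
    tolerable interval (c_L, c_R) around it at the configured error
    inflation.
    """

    left_label: int
    right_label: int
    cstar: float
    interval: tuple[float, float]

    @property
    def name(self) -> str:
        if self.right_label >= 1:
            return f"up-{self.right_label}"
        return f"down-{-self.left_label}"


@dataclass(frozen=True)
class CutoffSet:
    boundaries: tuple[Boundary, ...]
    model: MixtureModel

    def __post_init__(self) -> None:
        cs = [b.cstar for b in self.boundaries]
        if any(b >= a for a, b in zip(cs[1:], cs[:-1])):
            raise ValueError("boundary cutoffs must be strictly increasing")

    def by_name(self, name: str) -> Boundary:
        for b in self.boundaries:
            if b.name == name:
                return b
        raise KeyError(f"no boundary named {name}")


def pairwise_cutoff(left: Component, right: Component) -> float:
    """Equal-weight minimal-misclassification cutoff between two classes.

    Solves phi(x; mu_L, sd_L) = phi(x; mu_R, sd_R) for the root strictly
    between the two means. With equal SDs this is the midpoint; with
    unequal SDs the equality is a quadratic whose off-interval root is
    discarded. If no root lies between the means (pathological overlap)
    the SD-weighted midpoint is returned with a warning.
    """
    if not (left.mean < right.mean):
        raise ValueError("left component must have the smaller mean")
    m1, s1, m2, s2 = left.mean, left.sd, right.mean, right.sd
    if abs(s1 - s2) < 1e-12 * max(s1, s2):
        return 0.5 * (m1 + m2)
    # log-density equality: a x^2 + b x + c = 0
    a = 1.0 / (2 * s1 * s1) - 1.0 / (2 * s2 * s2)
    b = m2 / (s2 * s2) - m1 / (s1 * s1)
    c = m1 * m1 / (2 * s1 * s1) - m2 * m2 / (2 * s2 * s2) + math.log(s1 / s2)
    disc = b * b - 4 * a * c
    if disc >= 0:
        sq = math.sqrt(disc)
        for root in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
            if m1 < root < m2:
                return float(root)
    fallback = (m1 * s2 + m2 * s1) / (s1 + s2)
    log.warning(
        "no density-equality root between means %.4g and %.4g; using SD-weighted midpoint %.4g",
        m1, m2, fallback,
    )
    return float(fallback)


def _total_error(c: float, left: Component, right: Component) -> float:
    """Equal-weight total misclassification at cutoff c.

    P(X > c | left) + P(X < c | right), normal tails.
    """
    return float(norm.sf(c, left.mean, left.sd) + norm.cdf(c, right.mean, right.sd))


def cutoff_interval(left: Component, right: Component, r_tol: float) -> tuple[float, float]:
    """Tolerable interval around the minimal-misclassification cutoff.

    Returns the extreme points c_L <= c* <= c_R at which the total error
    equals (1 + r_tol) times its minimum, found by bracketed root search
    on each side of c*. The search is clamped at the two means when the
    inflated target is not reached (heavy overlap), with a warning.
    """
    if r_tol < 0:
        raise ValueError("r_tol must be nonnegative")
    cstar = pairwise_cutoff(left, right)
    if r_tol == 0:
        return (cstar, cstar)
    target = (1.0 + r_tol) * _total_error(cstar, left, right)

    def g(c: float) -> float:
        return _total_error(c, left, right) - target

    if g(left.mean) <= 0:
        c_lo = left.mean
        log.warning("tolerable interval clamped at left mean %.4g", left.mean)
    else:
        c_lo = brentq(g, left.mean, cstar, xtol=1e-12, rtol=1e-14)
    if g(right.mean) <= 0:
        c_hi = right.mean
        log.warning("tolerable interval clamped at right mean %.4g", right.mean)
    else:
        c_hi = brentq(g, cstar, right.mean, xtol=1e-12, rtol=1e-14)
    return (float(c_lo), float(c_hi))


def build_cutoffs(m: MixtureModel, r_tol: float = DEFAULT_R_TOL) -> CutoffSet:
    """One Boundary per adjacent class pair, in mean order."""
    if m.n_classes < 2:
        log.warning("single-class model: no cutoffs to compute")
        return CutoffSet(boundaries=(), model=m)
    bnds = []
    for a, b in zip(m.components[:-1], m.components[1:]):
        cstar = pairwise_cutoff(a, b)
        interval = cutoff_interval(a, b, r_tol)
        bnds.append(Boundary(left_label=a.label, right_label=b.label, cstar=cstar, interval=interval))
    return CutoffSet(boundaries=tuple(bnds), model=m)


def classify_proba(values, m: MixtureModel) -> np.ndarray:
    """MAP class labels; posterior ties resolve toward class 0."""
    values = np.atleast_1d(np.asarray(values, dtype=float))
    r = m.posteriors(values)
    labels = np.asarray(m.labels)
    # stable tie-break: among posteriors within 1e-12 of the max, pick
    # the label of smallest absolute value (toward the reference class)
    out = np.empty(values.size, dtype=int)
    for i in range(values.size):
        row = r[i]
        best = row.max()
        cand = np.flatnonzero(row >= best - 1e-12)
        out[i] = labels[cand[np.argmin(np.abs(labels[cand]))]]
    return out


def _interval_labels(values: np.ndarray, cuts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Assign interval labels; exact boundary hits go to the side nearer 0."""
    idx = np.searchsorted(cuts, values, side="left")  # ties fall left
    lab = labels[idx]
    # for boundaries below class 0 the nearer-zero side is the right one
    for j, c in enumerate(cuts):
        if labels[j + 1] <= 0:  # right side of boundary j is nearer class 0
            lab[values == c] = labels[j + 1]
    return lab


def classify_cutoff(values, cs: CutoffSet) -> np.ndarray:
    """Interval assignment at the minimal-misclassification cutoffs."""
    values = np.atleast_1d(np.asarray(values, dtype=float))
    labels = np.asarray(cs.model.labels)
    if not cs.boundaries:
        return np.full(values.size, labels[0], dtype=int)
    cuts = np.asarray([b.cstar for b in cs.boundaries])
    return _interval_labels(values, cuts, labels)


def classify_scutoff(values, cs: CutoffSet) -> np.ndarray:
    """Stringent cutoff: class-0-adjacent boundaries use interval ends.

    The boundary immediately above class 0 moves to its interval's right
    end and the one immediately below moves to its left end, so more
    values land in the reference-like class; all other boundaries keep
    their minimal-misclassification point.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    labels = np.asarray(cs.model.labels)
    if 0 not in labels:
        raise ValueError("stringent cutoff requires a class-0 component")
    if not cs.boundaries:
        return np.full(values.size, labels[0], dtype=int)
    cuts = []
    for b in cs.boundaries:
        if b.left_label == 0:  # boundary just above class 0
            cuts.append(b.interval[1])
        elif b.right_label == 0:  # boundary just below class 0
            cuts.append(b.interval[0])
        else:
            cuts.append(b.cstar)
    return _interval_labels(values, np.asarray(cuts), labels)


def summarize(labeled: dict[str, dict[str, np.ndarray]], values: dict[str, np.ndarray]):
    """Per cohort x rule x class summary: n, fraction, mean, median, SD.

    ``labeled`` maps cohort -> rule -> label vector; ``values`` maps
    cohort -> value vector. Empty classes appear with n=0 and blank
    statistics; singleton classes have blank SD.
    """
    import pandas as pd

    rows = []
    for cohort, per_rule in labeled.items():
        v = np.asarray(values[cohort], dtype=float)
        for rule, lab in per_rule.items():
            lab = np.asarray(lab)
            all_labels = sorted(set(lab.tolist()))
            for cls in all_labels:
                sel = v[lab == cls]
                n = sel.size
                rows.append(
                    {
                        "cohort": cohort,
                        "rule": rule,
                        "class": cls,
                        "n": n,
                        "fraction_pct": 100.0 * n / v.size if v.size else np.nan,
                        "mean": float(np.mean(sel)) if n else np.nan,
                        "median": float(np.median(sel)) if n else np.nan,
                        "sd": float(np.std(sel, ddof=1)) if n > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def heatmap_matrix(
    labels_by_analyte: dict[str, np.ndarray], annotation: np.ndarray | None = None
):
    """Samples x analytes integer class matrix for heatmap rendering.

    All label vectors must describe the same ordered cohort; an analyte
    missing the cohort may pass None and yields a column of missing
    markers. Returns (DataFrame, scale) where scale is the symmetric
    color-limit |label| max for a diverging palette centered on 0.
    """
    import pandas as pd

    n = max(np.asarray(v).size for v in labels_by_analyte.values() if v is not None)
    cols = {}
    for name, lab in labels_by_analyte.items():
        if lab is None:
            cols[name] = np.full(n, np.nan)
        else:
            lab = np.asarray(lab, dtype=float)
            if lab.size != n:
                raise ValueError(f"analyte {name}: cohort length {lab.size} != {n}")
            cols[name] = lab
    df = pd.DataFrame(cols)
    if annotation is not None:
        df.insert(0, "annotation", np.asarray(annotation, dtype=float))
    scale = float(np.nanmax(np.abs(df.to_numpy()))) if df.size else 1.0
    return df, max(scale, 1.0)
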