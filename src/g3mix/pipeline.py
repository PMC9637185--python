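"""End-to-end orchestration: fit, classify and summarize every analyte.

This is the library surface the command-line front end wraps: one call
fits the semi-constrained mixture per analyte, builds the cutoff set, and
applies the three classification rules to the test, reference and every
query cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import (
    DEFAULT_R_TOL,
    CutoffSet,
    build_cutoffs,
    classify_cutoff,
    classify_proba,
    classify_scutoff,
    summarize,
)
from .data_io import AnalyteData, Dataset
from .em import EMOptions, W0_WARN, reference_stats, select_model
from .mixture import FitMeta, MixtureModel

__all__ = ["AnalyteResult", "fit_analyte", "classify_analyte", "run_pipeline"]

log = logging.getLogger(__name__)

RULES = ("proba", "cutoff", "scutoff")


@dataclass
class AnalyteResult:
    """Everything computed for one analyte."""

    name: str
    model: MixtureModel
    meta: FitMeta
    cutoffs: CutoffSet
    labels: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    summary: object = None
    proba_reference_valid: bool = True


def fit_analyte(analyte: AnalyteData, opts: EMOptions | None = None):
    """Reference stats + BIC-selected semi-constrained mixture for one analyte."""
    opts = opts or EMOptions()
    ref = reference_stats(analyte.ref)
    model, meta = select_model(analyte.test, ref, opts)
    return model, meta


def classify_analyte(
    analyte: AnalyteData,
    model: MixtureModel,
    meta: FitMeta,
    r_tol: float = DEFAULT_R_TOL,
) -> AnalyteResult:
    """Apply proba/cutoff/s.cutoff to every cohort of one analyte."""
    cs = build_cutoffs(model, r_tol)
    labels: dict[str, dict[str, np.ndarray]] = {}
    for cohort, values in analyte.cohorts().items():
        labels[cohort] = {
            "proba": classify_proba(values, model),
            "cutoff": classify_cutoff(values, cs),
            "scutoff": classify_scutoff(values, cs),
        }
    w0 = model.component(0).weight if 0 in model.labels else 0.0
    res = AnalyteResult(
        name=analyte.name,
        model=model,
        meta=meta,
        cutoffs=cs,
        labels=labels,
        proba_reference_valid=w0 >= W0_WARN,
    )
    res.summary = summarize(labels, analyte.cohorts())
    return res


def run_pipeline(
    dataset: Dataset, opts: EMOptions | None = None, r_tol: float = DEFAULT_R_TOL
) -> dict[str, AnalyteResult]:
    """Fit + classify every analyte; failures are logged, not fatal."""
    opts = opts or EMOptions()
    results: dict[str, AnalyteResult] = {}
    for analyte in dataset:
        try:
            model, meta = fit_analyte(analyte, opts)
            results[analyte.name] = classify_analyte(analyte, model, meta, r_tol)
        except Exception:  # noqa: BLE001 - other analytes still processed
            log.exception("analyte %s failed", analyte.name)
    if not results:
        raise RuntimeError("all analytes failed")
    return results
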