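"""Resampling-based stability of class number, means and cutoffs.

Subsamples a fraction of the test and/or reference cohort without
replacement (with replacement would risk manufacturing false classes out
of repeated far-tail events), refits the full model-selection pipeline on
each resample, and tabulates the class count, per-class means, and the
class-0-adjacent diagnostic cutoffs (down-1, up-1) plus up-2 across
resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import DEFAULT_R_TOL, build_cutoffs
from .em import EMOptions, reference_stats, select_model

__all__ = ["ResampleConfig", "ResampleReport", "resample_fit"]

log = logging.getLogger(__name__)

MAX_RESAMPLES = 100
_TRACKED = ("down-1", "up-1", "up-2")


@dataclass
class ResampleConfig:
    """fraction in (0, 1]; n_resamples capped at 100; scope test/ref/both."""

    fraction: float = 0.8
    n_resamples: int = 100
    scope: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        if not 1 <= self.n_resamples <= MAX_RESAMPLES:
            raise ValueError(f"n_resamples must lie in [1, {MAX_RESAMPLES}]")
        if self.scope not in {"test", "ref", "both"}:
            raise ValueError("scope must be one of test/ref/both")


@dataclass
class ResampleReport:
    records: pd.DataFrame  # one row per resample (failures flagged, not dropped)
    summary: pd.DataFrame  # min/max/median/SD per tracked quantity
    g_distribution: dict[int, int]


def _subsample(rng: np.random.Generator, values: np.ndarray, fraction: float) -> np.ndarray:
    m = int(np.floor(fraction * values.size))
    idx = rng.choice(values.size, size=m, replace=False)
    return values[idx]


def resample_fit(analyte, opts: EMOptions, rcfg: ResampleConfig, r_tol: float = DEFAULT_R_TOL) -> ResampleReport:
    """Refit the model on each resample and tabulate parameter variability.

    When the reference is in scope, class-0 constraints are re-derived
    from the subsampled reference; otherwise the full-reference stats are
    reused. Fully reproducible from the configured seed.
    """
    rng = np.random.default_rng(rcfg.seed)
    full_ref = reference_stats(analyte.ref)
    records = []
    n_fail = 0
    for i in range(rcfg.n_resamples):
        test = (
            _subsample(rng, analyte.test, rcfg.fraction)
            if rcfg.scope in ("test", "both")
            else analyte.test
        )
        ref_vals = (
            _subsample(rng, analyte.ref, rcfg.fraction)
            if rcfg.scope in ("ref", "both")
            else None
        )
        rec: dict = {"resample": i, "failed": False}
        try:
            ref = reference_stats(ref_vals) if ref_vals is not None else full_ref
            model, meta = select_model(test, ref, opts)
            cs = build_cutoffs(model, r_tol)
            rec["n_classes"] = model.n_classes
            rec["bic"] = meta.bic
            for c in model.components:
                rec[f"mean_{c.label}"] = c.mean
            for name in _TRACKED:
                try:
                    rec[name] = cs.by_name(name).cstar
                except KeyError:
                    pass
        except Exception as exc:  # noqa: BLE001 - failures recorded per resample
            rec["failed"] = True
            rec["error"] = str(exc)
            n_fail += 1
        records.append(rec)
    if n_fail > rcfg.n_resamples / 2:
        log.warning("%d/%d resamples failed", n_fail, rcfg.n_resamples)

    df = pd.DataFrame(records)
    ok = df[~df["failed"]]
    quantities = ["n_classes"] + [c for c in df.columns if c.startswith("mean_")] + [
        n for n in _TRACKED if n in df.columns
    ]
    summary_rows = []
    for q in quantities:
        col = ok[q].dropna() if q in ok else pd.Series(dtype=float)
        if col.empty:
            continue
        summary_rows.append(
            {
                "quantity": q,
                "n": int(col.size),
                "min": float(col.min()),
                "median": float(col.median()),
                "max": float(col.max()),
                "sd": float(col.std(ddof=1)) if col.size > 1 else np.nan,
            }
        )
    gdist = ok["n_classes"].value_counts().to_dict() if "n_classes" in ok else {}
    return ResampleReport(
        records=df,
        summary=pd.DataFrame(summary_rows),
        g_distribution={int(k): int(v) for k, v in gdist.items()},
    )
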