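"""Tabular input/output for multi-analyte measurement files.

One CSV/TSV file carries every analyte and cohort. Columns are grouped by
a suffix convention on the header names:

    <analyte>                  test cohort (the cohort the model is learned on)
    <analyte>_ref              reference cohort (supplies class-0 constraints)
    <analyte>_query_<cohort>   any number of named query cohorts
    <analyte>_truth_<cohort>   optional 0/1 truth labels for diagnostics

Blank cells and the tokens NA/NaN (case-insensitive) are dropped per
column, so cohorts may have unequal lengths; row identity across cohorts
is not assumed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .em import MIN_N_DEFAULT

__all__ = ["AnalyteData", "Dataset", "read_table", "write_results"]

_NA_TOKENS = {"", "na", "nan"}


@dataclass
class AnalyteData:
    """Test, reference and query value vectors for one named analyte."""

    name: str
    test: np.ndarray
    ref: np.ndarray
    queries: dict[str, np.ndarray] = field(default_factory=dict)
    truth: dict[str, np.ndarray] = field(default_factory=dict)

    def cohorts(self) -> dict[str, np.ndarray]:
        out = {"test": self.test, "ref": self.ref}
        out.update({f"query_{k}": v for k, v in self.queries.items()})
        return out


@dataclass
class Dataset:
    analytes: list[AnalyteData]

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("analyte names must be unique")

    def __iter__(self):
        return iter(self.analytes)

    def __getitem__(self, name: str) -> AnalyteData:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]


def _clean_column(raw: pd.Series, col: str) -> np.ndarray:
    """Drop blanks/NA tokens, parse the rest as floats with coordinates on error."""
    vals = []
    for i, cell in raw.items():
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            continue
        s = str(cell).strip()
        if s.lower() in _NA_TOKENS:
            continue
        try:
            x = float(s)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell at row {i + 2}, column '{col}': {s!r}") from exc
        if not np.isfinite(x):
            continue
        vals.append(x)
    return np.asarray(vals, dtype=float)


def _detect_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(64 * 1024)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_table(path, sep: str | None = None, min_n: int = MIN_N_DEFAULT) -> Dataset:
    """Read a multi-analyte table into a Dataset.

    Column roles follow the suffix convention documented in the module
    docstring; analyte order follows the order of the test columns in the
    header. Missing test or reference columns, non-numeric cells, and
    cohorts shorter than ``min_n`` are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True)
    cols = [c.strip() for c in df.columns]
    df.columns = cols

    roles: dict[str, dict] = {}
    order: list[str] = []
    for col in cols:
        if "_ref" == col[-4:]:
            roles.setdefault(col[:-4], {})["ref"] = col
        elif "_query_" in col:
            name, cohort = col.split("_query_", 1)
            roles.setdefault(name, {}).setdefault("queries", {})[cohort] = col
        elif "_truth_" in col:
            name, cohort = col.split("_truth_", 1)
            roles.setdefault(name, {}).setdefault("truth", {})[cohort] = col
        else:
            roles.setdefault(col, {})["test"] = col
            order.append(col)

    analytes = []
    for name in order + [n for n in roles if n not in order]:
        spec = roles[name]
        if "test" not in spec:
            raise ValueError(f"analyte {name} lacks test column")
        if "ref" not in spec:
            raise ValueError(f"analyte {name} lacks reference column")
        test = _clean_column(df[spec["test"]], spec["test"])
        ref = _clean_column(df[spec["ref"]], spec["ref"])
        for label, vec in (("test", test), ("ref", ref)):
            if vec.size < min_n:
                raise ValueError(
                    f"analyte {name}, cohort {label}: {vec.size} values < min_n={min_n}"
                )
        queries = {}
        for cohort, col in spec.get("queries", {}).items():
            q = _clean_column(df[col], col)
            if q.size < min_n:
                raise ValueError(
                    f"analyte {name}, cohort query_{cohort}: {q.size} values < min_n={min_n}"
                )
            queries[cohort] = q
        truth = {
            cohort: _clean_column(df[col], col).astype(int)
            for cohort, col in spec.get("truth", {}).items()
        }
        analytes.append(AnalyteData(name=name, test=test, ref=ref, queries=queries, truth=truth))
    return Dataset(analytes=analytes)


def write_dataset(dataset: Dataset, path, sep: str = ",") -> None:
    """Write a Dataset back to one table in the suffix convention."""
    columns: dict[str, np.ndarray] = {}
    for a in dataset:
        columns[a.name] = a.test
        columns[f"{a.name}_ref"] = a.ref
        for cohort, v in a.queries.items():
            columns[f"{a.name}_query_{cohort}"] = v
        for cohort, v in a.truth.items():
            columns[f"{a.name}_truth_{cohort}"] = v
    n = max(v.size for v in columns.values())
    padded = {
        k: np.concatenate([v.astype(float), np.full(n - v.size, np.nan)]) for k, v in columns.items()
    }
    pd.DataFrame(padded).to_csv(path, sep=sep, index=False)


def write_results(dataset: Dataset, models, classifications, summaries, cutoffs, outdir) -> list[Path]:
    """Emit per-analyte CSVs: model, per-cohort class labels, summary, cutoffs.

    ``models`` maps analyte -> (MixtureModel, FitMeta); ``classifications``
    maps analyte -> cohort -> rule -> label vector; ``summaries`` maps
    analyte -> summary DataFrame; ``cutoffs`` maps analyte -> CutoffSet.
    Numbers are written at full double precision; column order is fixed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for a in dataset:
        adir = outdir / a.name
        adir.mkdir(exist_ok=True)
        model, meta = models[a.name]
        rows = [
            {
                "class": c.label,
                "mean": c.mean,
                "sd": c.sd,
                "weight": c.weight,
                "frozen": c.frozen,
                "bic": meta.bic,
                "bin_count": meta.bin_count,
            }
            for c in model.components
        ]
        p = adir / "model.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

        for cohort, per_rule in classifications[a.name].items():
            vals = a.cohorts()[cohort]
            df = pd.DataFrame({"value": vals})
            for rule, lab in per_rule.items():
                df[rule] = lab
            p = adir / f"classes_{cohort}.csv"
            df.to_csv(p, index=False)
            written.append(p)

        p = adir / "summary.csv"
        summaries[a.name].to_csv(p, index=False)
        written.append(p)

        cs = cutoffs[a.name]
        cdf = pd.DataFrame(
            [
                {
                    "boundary": b.name,
                    "left_class": b.left_label,
                    "right_class": b.right_label,
                    "cutoff": b.cstar,
                    "interval_left": b.interval[0],
                    "interval_right": b.interval[1],
                }
                for b in cs.boundaries
            ]
        )
        p = adir / "cutoffs.csv"
        cdf.to_csv(p, index=False)
        written.append(p)
    return written
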