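"""Deterministic generators of mixture-structured analyte data.

These emulate the structure of multiplex mRNA signal measurements: a test
cohort drawn from a multi-component Gaussian mixture in which one
component coincides with the healthy-reference distribution, a reference
cohort drawn from that component alone, and query cohorts drawn from the
full mixture on independent RNG streams. Measurements are nonnegative
signal intensities, so draws are left-truncated at 0 by rejection.

``erbb2_like`` reproduces the published 4-class parameterization of an
ERBB2 mRNA test model (class 0: 40.4 +/- 13.6, weight 0.46; class 1:
88.7 +/- 48.9, weight 0.38; class 2: 403 +/- 189, weight 0.14; class 3:
879 +/- 29.1, weight 0.02) with the cohort sizes of the original study
(142 test, 34 reference, 75 query).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AnalyteData

__all__ = ["SyntheticSpec", "generate", "erbb2_like", "ERBB2_4CLASS"]

# (mean, sd, weight) per class of the published 4-class ERBB2 test model
ERBB2_4CLASS: tuple[tuple[float, float, float], ...] = (
    (40.4, 13.6, 0.46),
    (88.7, 48.9, 0.38),
    (403.0, 189.0, 0.14),
    (879.0, 29.1, 0.02),
)


@dataclass
class SyntheticSpec:
    """Mixture recipe: components (mean, sd, weight), cohort sizes, seed."""

    components: tuple[tuple[float, float, float], ...]
    n_test: int = 200
    n_ref: int = 50
    n_query: int = 100
    ref_component_index: int = 0
    seed: int = 0
    truncate_at_zero: bool = False
    name: str = "synthetic"
    query_name: str = "q1"

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w}")
        if any(c[1] <= 0 for c in self.components):
            raise ValueError("all component sds must be positive")
        if not 0 <= self.ref_component_index < len(self.components):
            raise ValueError("ref_component_index out of range")


def _draw_component(rng: np.random.Generator, mean: float, sd: float, n: int, truncate: bool) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    if truncate:
        while True:  # rejection: redraw negatives (far-left tail only)
            bad = out < 0
            if not bad.any():
                break
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return out


def _draw_mixture(rng: np.random.Generator, spec: SyntheticSpec, n: int) -> tuple[np.ndarray, np.ndarray]:
    weights = np.asarray([c[2] for c in spec.components])
    origin = rng.choice(len(spec.components), size=n, p=weights)
    values = np.empty(n)
    for j, (mean, sd, _w) in enumerate(spec.components):
        sel = origin == j
        if sel.any():
            values[sel] = _draw_component(rng, mean, sd, int(sel.sum()), spec.truncate_at_zero)
    return values, origin


def generate(spec: SyntheticSpec) -> tuple[AnalyteData, dict[str, np.ndarray]]:
    """Draw one analyte's cohorts; returns (data, component-of-origin labels).

    Test and query are drawn from the full mixture on independent RNG
    streams; the reference comes from the reference component only.
    Bitwise reproducible from the seed.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(3)
    rng_test, rng_ref, rng_query = (np.random.default_rng(s) for s in seeds)

    test, test_origin = _draw_mixture(rng_test, spec, spec.n_test)
    rm, rs, _rw = spec.components[spec.ref_component_index]
    ref = _draw_component(rng_ref, rm, rs, spec.n_ref, spec.truncate_at_zero)
    query, query_origin = _draw_mixture(rng_query, spec, spec.n_query)

    data = AnalyteData(
        name=spec.name,
        test=test,
        ref=ref,
        queries={spec.query_name: query},
    )
    origins = {
        "test": test_origin,
        "ref": np.full(spec.n_ref, spec.ref_component_index),
        f"query_{spec.query_name}": query_origin,
    }
    return data, origins


def erbb2_like(seed: int = 0) -> tuple[AnalyteData, dict[str, np.ndarray]]:
    """ERBB2-style 4-class analyte with the original study's cohort sizes."""
    spec = SyntheticSpec(
        components=ERBB2_4CLASS,
        n_test=142,
        n_ref=34,
        n_query=75,
        ref_component_index=0,
        seed=seed,
        truncate_at_zero=True,
        name="ERBB2",
        query_name="DCIS",
    )
    return generate(spec)
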