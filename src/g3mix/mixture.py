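"""Univariate Gaussian mixture data model with one frozen reference class.

A mixture here is a weighted sum of normal densities, one per class. The
class labeled 0 is the *reference-like* class: its mean and standard
deviation are pinned to statistics of an independent reference cohort and
only its weight is learned. Classes below it in mean carry negative
integer labels (-1, -2, ...), classes above it positive ones (1, 2, ...);
the larger the absolute label, the farther the class sits from the
reference.

All likelihood computations run in log space (log-sum-exp over
components), so posteriors and log-likelihoods are well defined for any
finite input even deep in the tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Component",
    "ReferenceStats",
    "FitMeta",
    "MixtureModel",
    "component_density",
    "mixture_density",
    "log_likelihood",
    "bic",
    "posteriors",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Component:
    """One Gaussian class: integer label, mean/sd in analyte units, weight.

    ``frozen`` marks the reference-constrained class 0 whose mean and sd
    are never updated by the fitting algorithm.
    """

    label: int
    mean: float
    sd: float
    weight: float
    frozen: bool = False

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError(f"component sd must be positive, got {self.sd}")
        if not (-1e-9 <= self.weight <= 1 + 1e-9):
            raise ValueError(f"component weight must lie in [0, 1], got {self.weight}")

    def logpdf(self, x):
        z = (np.asarray(x, dtype=float) - self.mean) / self.sd
        return -0.5 * (z * z + _LOG_2PI) - math.log(self.sd)

    def pdf(self, x):
        return np.exp(self.logpdf(x))


@dataclass(frozen=True)
class ReferenceStats:
    """Mean, sample SD (n-1 denominator) and size of the reference cohort."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError("degenerate reference: sd must be positive")


@dataclass
class FitMeta:
    """Bookkeeping for one EM fit: likelihood, BIC, init bin count, iterations."""

    loglik: float
    bic: float
    bin_count: int
    iterations: int
    converged: bool
    warnings: list[str] = field(default_factory=list)


class MixtureModel:
    """Ordered Gaussian components with integer class labels.

    Components are kept sorted by increasing mean; labels are consecutive
    integers with 0 on the frozen reference component (when present),
    negatives below and positives above.
    """

    def __init__(self, components: list[Component], n_train: int = 0):
        comps = sorted(components, key=lambda c: c.mean)
        if not comps:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        n_frozen = sum(c.frozen for c in comps)
        if n_frozen > 1:
            raise ValueError("at most one frozen (class 0) component allowed")
        self.components = comps
        self.n_train = int(n_train)
        self._means = np.array([c.mean for c in comps])
        self._sds = np.array([c.sd for c in comps])
        self._logw = np.log(np.maximum([c.weight for c in comps], 1e-300))

    # -- structure ------------------------------------------------------
    @property
    def n_classes(self) -> int:
        return len(self.components)

    @property
    def labels(self) -> list[int]:
        return [c.label for c in self.components]

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self._logw)

    def frozen_index(self) -> int | None:
        for i, c in enumerate(self.components):
            if c.frozen:
                return i
        return None

    def component(self, label: int) -> Component:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"no component with label {label}")

    @staticmethod
    def assign_labels(components: list[Component]) -> "MixtureModel":
        """Relabel by mean order with 0 on the frozen component.

        If no component is frozen, labels start at 0 on the lowest mean.
        """
        comps = sorted(components, key=lambda c: c.mean)
        izero = next((i for i, c in enumerate(comps) if c.frozen), 0)
        relabeled = [replace(c, label=i - izero) for i, c in enumerate(comps)]
        return MixtureModel(relabeled)

    def with_n_train(self, n: int) -> "MixtureModel":
        m = MixtureModel(self.components, n_train=n)
        return m

    # -- densities ------------------------------------------------------
    def component_logpdfs(self, x) -> np.ndarray:
        """Matrix of log w_c + log phi(x; mu_c, sd_c), shape (len(x), G)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self._means[None, :]) / self._sds[None, :]
        return self._logw[None, :] - 0.5 * (z * z + _LOG_2PI) - np.log(self._sds)[None, :]

    def logpdf(self, x):
        lp = logsumexp(self.component_logpdfs(x), axis=1)
        return lp if np.ndim(x) else float(lp[0])

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def posteriors(self, x) -> np.ndarray:
        """Responsibilities r_c(x), rows summing to 1; shape (len(x), G)."""
        lp = self.component_logpdfs(x)
        lp = lp - logsumexp(lp, axis=1, keepdims=True)
        r = np.exp(lp)
        return r if np.ndim(x) else r[0]

    def log_likelihood(self, values) -> float:
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("log-likelihood of an empty sample is undefined")
        return float(np.sum(self.logpdf(values)))

    def n_free_parameters(self) -> int:
        """3(G-1): G-1 free weights plus mean and sd of each non-frozen class.

        Class-0 mean/sd are constants supplied by the reference; the weight
        vector loses one degree of freedom to normalization, and w0 counts
        as free.
        """
        return 3 * (self.n_classes - 1)

    def bic(self, values) -> float:
        n = np.asarray(values).size
        return self.n_free_parameters() * math.log(n) - 2.0 * self.log_likelihood(values)

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{c.label}: N({c.mean:.4g}, {c.sd:.4g}) w={c.weight:.4g}{'*' if c.frozen else ''}"
            for c in self.components
        )
        return f"MixtureModel({parts})"


# -- functional wrappers (convenience mirror of the method API) ----------

def component_density(x, c: Component):
    """Normal density phi(x; c.mean, c.sd)."""
    return c.pdf(x)


def mixture_density(x, m: MixtureModel):
    """Weighted sum of component densities at x."""
    return m.pdf(x)


def log_likelihood(values, m: MixtureModel) -> float:
    return m.log_likelihood(values)


def bic(values, m: MixtureModel) -> float:
    """p ln n - 2 ln L with p = 3(G-1); n is the training-sample size."""
    return m.bic(values)


def posteriors(x, m: MixtureModel) -> np.ndarray:
    return m.posteriors(x)
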