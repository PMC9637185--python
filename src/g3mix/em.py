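"""Semi-constrained EM: histogram-peak initialization, fitting, BIC selection.

The fitting problem is a univariate Gaussian mixture where one component
("class 0") has its mean and SD frozen to the reference-cohort statistics
while its weight remains free; all other components are fully free. The
number of free components is decided by the data: the EM is initialized
with one component per histogram peak of the test sample, and after each
converged run starved components are removed (*vanishing*) and
near-coincident ones merged (*fusion*); if the structure changed, EM is
re-run until the component set is stable. Running this over a vector of
histogram bin counts and keeping the fit with the lowest BIC gives the
selected model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .mixture import Component, FitMeta, MixtureModel, ReferenceStats

__all__ = [
    "EMOptions",
    "Peak",
    "reference_stats",
    "histogram_peaks",
    "init_model",
    "em_fit",
    "vanish",
    "fuse",
    "select_model",
]

log = logging.getLogger(__name__)

DEFAULT_BIN_COUNTS = (10, 15, 20, 25, 30, 35, 40)
MIN_N_DEFAULT = 5

# class-0 weight below this triggers the "proba classification of the
# reference may be invalid" warning
W0_WARN = 0.01


@dataclass
class EMOptions:
    """Tuning knobs of the semi-constrained EM.

    bin_counts : histogram sizes tried at initialization; the fit with the
        lowest BIC wins.
    tol : relative log-likelihood change declaring convergence.
    max_iter : iteration cap per EM run.
    t_fuse : adjacent components closer than ``t_fuse * min(sd_i, sd_j)``
        in mean are merged (dimensionless).
    t_vanish : free components supported by fewer than this many expected
        values (n * weight) are removed.
    min_n : minimum retained values per cohort.
    seed : RNG seed for any stochastic option (resampling etc.).
    """

    bin_counts: tuple[int, ...] = DEFAULT_BIN_COUNTS
    tol: float = 1e-10
    max_iter: int = 500
    t_fuse: float = 1.0
    t_vanish: float = 2.0
    min_n: int = MIN_N_DEFAULT
    log10: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bin_counts:
            raise ValueError("bin_counts must be nonempty")
        if self.t_fuse <= 0:
            raise ValueError("t_fuse must be positive")
        if self.t_vanish < 0:
            raise ValueError("t_vanish must be nonnegative")


@dataclass(frozen=True)
class Peak:
    """A local maximum of the test histogram: bin-run midpoint and width."""

    center: float
    height: int
    halfwidth: float


def reference_stats(ref_values) -> ReferenceStats:
    """Arithmetic mean and sample SD (n-1 denominator) of the reference."""
    v = np.asarray(ref_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("reference needs at least two finite values")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate reference: zero variance")
    return ReferenceStats(mean=float(np.mean(v)), sd=sd, n=int(v.size))


def histogram_peaks(test_values, k: int) -> list[Peak]:
    """Peaks of the equal-width k-bin histogram spanning [min, max].

    A peak is a maximal run of equal-count bins whose count strictly
    exceeds both flanking bins; a run touching the histogram boundary only
    needs to exceed its single inner neighbor. The peak center is the
    midpoint of the run and the halfwidth is one bin width.
    """
    v = np.asarray(test_values, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 bins")
    counts, edges = np.histogram(v, bins=k)
    width = edges[1] - edges[0]
    mids = 0.5 * (edges[:-1] + edges[1:])

    peaks: list[Peak] = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and counts[j + 1] == counts[i]:
            j += 1
        left_ok = i == 0 or counts[i] > counts[i - 1]
        right_ok = j == k - 1 or counts[j] > counts[j + 1]
        # an all-flat histogram (run spans everything) is not a peak
        if left_ok and right_ok and counts[i] > 0 and not (i == 0 and j == k - 1):
            peaks.append(
                Peak(center=float(0.5 * (mids[i] + mids[j])), height=int(counts[i]), halfwidth=float(width))
            )
        i = j + 1
    return peaks


def _sd_floor(values) -> float:
    rng = float(np.max(values) - np.min(values))
    return max(1e-6 * rng, 1e-12)


def init_model(peaks: list[Peak], ref: ReferenceStats, n: int) -> MixtureModel:
    """Initial mixture: one free component per peak plus the frozen class 0.

    Peaks whose center lies within one halfwidth of the reference mean are
    dropped (they would duplicate class 0). Initial SD of a free component
    is the bin width, initial weights are equal across all components.
    """
    free = [p for p in peaks if abs(p.center - ref.mean) >= p.halfwidth]
    g = len(free) + 1
    w = 1.0 / g
    comps = [Component(label=0, mean=ref.mean, sd=ref.sd, weight=w, frozen=True)]
    for p in free:
        comps.append(Component(label=99, mean=p.center, sd=max(p.halfwidth, 1e-12), weight=w))
    return MixtureModel.assign_labels(comps)


def vanish(m: MixtureModel, n: int, t_vanish: float) -> MixtureModel:
    """Remove free components with fewer than t_vanish expected values.

    The frozen class 0 is exempt (a warning is logged if it starves);
    remaining weights are renormalized.
    """
    keep = []
    for c in m.components:
        if c.frozen:
            if n * c.weight < t_vanish:
                log.warning("class 0 supported by %.2f expected values; retained (frozen)", n * c.weight)
            keep.append(c)
        elif n * c.weight >= t_vanish:
            keep.append(c)
    total = sum(c.weight for c in keep)
    keep = [replace(c, weight=c.weight / total) for c in keep]
    return MixtureModel.assign_labels(keep)


def _moment_merge(a: Component, b: Component) -> Component:
    """Moment-matched merge of two free components (weight sum preserved)."""
    w = a.weight + b.weight
    mu = (a.weight * a.mean + b.weight * b.mean) / w
    var = (
        a.weight * (a.sd ** 2 + (a.mean - mu) ** 2)
        + b.weight * (b.sd ** 2 + (b.mean - mu) ** 2)
    ) / w
    return Component(label=99, mean=mu, sd=math.sqrt(var), weight=w)


def fuse(m: MixtureModel, t_fuse: float) -> MixtureModel:
    """Merge adjacent components closer than t_fuse * min(sd_i, sd_j).

    The closest qualifying pair is merged first; merging repeats until no
    pair qualifies. A free component fusing with the frozen class 0
    donates its weight to class 0, whose mean and SD stay fixed.
    """
    comps = sorted(m.components, key=lambda c: c.mean)
    while len(comps) > 1:
        best = None
        best_gap = np.inf
        for i in range(len(comps) - 1):
            a, b = comps[i], comps[i + 1]
            gap = abs(b.mean - a.mean) / (t_fuse * min(a.sd, b.sd))
            if gap < 1.0 and gap < best_gap:
                best, best_gap = i, gap
        if best is None:
            break
        a, b = comps[best], comps[best + 1]
        if a.frozen or b.frozen:
            fro, free_ = (a, b) if a.frozen else (b, a)
            merged = replace(fro, weight=fro.weight + free_.weight)
            log.info("fused free component N(%.4g, %.4g) into class 0", free_.mean, free_.sd)
        else:
            merged = _moment_merge(a, b)
        comps[best : best + 2] = [merged]
    return MixtureModel.assign_labels(comps)


def _em_iterate(values: np.ndarray, model: MixtureModel, ref: ReferenceStats, opts: EMOptions):
    """One EM run to convergence; structure unchanged. Returns (model, ll, iters, conv)."""
    n = values.size
    floor = _sd_floor(values)
    ll_prev = model.log_likelihood(values)
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        r = model.posteriors(values)  # (n, G)
        nk = r.sum(axis=0)
        w = nk / n
        comps = []
        for j, c in enumerate(model.components):
            if c.frozen or nk[j] <= 0:
                comps.append(replace(c, weight=max(w[j], 0.0)))
            else:
                mu = float(r[:, j] @ values / nk[j])
                var = float(r[:, j] @ (values - mu) ** 2 / nk[j])
                comps.append(replace(c, weight=w[j], mean=mu, sd=max(math.sqrt(max(var, 0.0)), floor)))
        total = sum(c.weight for c in comps)
        comps = [replace(c, weight=c.weight / total) for c in comps]
        model = MixtureModel.assign_labels(comps)
        ll = model.log_likelihood(values)
        if ll < ll_prev - 1e-8 * max(1.0, abs(ll_prev)):
            log.warning("log-likelihood decreased within EM run (%.6g -> %.6g)", ll_prev, ll)
        if abs(ll - ll_prev) <= opts.tol * max(1.0, abs(ll_prev)):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
    return model, ll_prev, it, converged


def em_fit(
    test_values,
    init: MixtureModel,
    ref: ReferenceStats,
    opts: EMOptions | None = None,
    bin_count: int = 0,
) -> tuple[MixtureModel, FitMeta]:
    """Run semi-constrained EM from ``init`` with vanish/fuse stabilization.

    The E-step computes responsibilities under the current mixture; the
    M-step updates every weight as the mean responsibility but updates
    mean/SD only for non-frozen components. After convergence, vanishing
    is applied before fusion; if either changed the component set, EM is
    re-run, until the structure is stable.
    """
    opts = opts or EMOptions()
    values = np.asarray(test_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < opts.min_n:
        raise ValueError(f"need at least {opts.min_n} test values, got {values.size}")

    model = init
    total_iters = 0
    warnings: list[str] = []
    for _round in range(20):  # structural-edit rounds; EM converges inside each
        model, ll, iters, converged = _em_iterate(values, model, ref, opts)
        total_iters += iters
        edited = vanish(model, values.size, opts.t_vanish)
        edited = fuse(edited, opts.t_fuse)
        if edited.n_classes == model.n_classes:
            model = edited
            break
        warnings.append(f"structure edited: {model.n_classes} -> {edited.n_classes} classes")
        model = edited
    model = model.with_n_train(values.size)
    ll = model.log_likelihood(values)
    w0 = model.component(0).weight if 0 in model.labels else 0.0
    if w0 < W0_WARN:
        msg = "class-0 weight close to null; proba classification of reference may be invalid"
        warnings.append(msg)
        log.warning(msg)
    meta = FitMeta(
        loglik=ll,
        bic=model.bic(values),
        bin_count=bin_count,
        iterations=total_iters,
        converged=converged,
        warnings=warnings,
    )
    return model, meta


def select_model(
    test_values, ref: ReferenceStats, opts: EMOptions | None = None
) -> tuple[MixtureModel, FitMeta]:
    """Fit one model per histogram bin count and keep the lowest-BIC fit.

    Ties are broken toward fewer classes, then toward the smaller bin
    count. Deterministic given (values, ref, opts).
    """
    opts = opts or EMOptions()
    values = np.asarray(test_values, dtype=float)
    values = values[np.isfinite(values)]
    if opts.log10:
        values = np.log10(values)

    best: tuple[float, int, int] | None = None
    best_fit: tuple[MixtureModel, FitMeta] | None = None
    errors: list[str] = []
    for k in sorted(set(opts.bin_counts)):
        try:
            peaks = histogram_peaks(values, k)
            init = init_model(peaks, ref, values.size)
            model, meta = em_fit(values, init, ref, opts, bin_count=k)
        except Exception as exc:  # noqa: BLE001 - per-k failure is recoverable
            errors.append(f"k={k}: {exc}")
            continue
        key = (meta.bic, model.n_classes, k)
        if best is None or key < best:
            best, best_fit = key, (model, meta)
    if best_fit is None:
        raise RuntimeError("no supportable model; all fits failed: " + "; ".join(errors))
    return best_fit
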