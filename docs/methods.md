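# Methods

## Model

Each analyte is modeled per cohort of continuous measurements as a
univariate Gaussian mixture

    f(x) = sum_c  w_c * phi(x; mu_c, sigma_c),

with one component per class. The class labeled 0 is *reference-like*:
its mean and standard deviation are fixed to the sample statistics of an
independent reference cohort (mean and n−1 SD), and only its weight w_0
is learned from the test cohort. Every other component is fully free.
Classes are labeled by mean order relative to class 0 with consecutive
integers: negative below, positive above; a larger |label| means farther
from the reference. This *semi-constrained* formulation embeds prior
knowledge of the healthy/control distribution into the test model, which
is the substantive difference from unconstrained mixture fitting: the
reference-like mode cannot drift toward a disease-related mode even when
the two overlap heavily.

The model is learned on the test cohort only. Reference and query
cohorts are then classified with the learned test model.

### Fitting

EM with the constraint applied in the M-step: responsibilities are
computed for all components (E-step); weights update as mean
responsibilities for *all* components including class 0; means and SDs
update by responsibility weighting only for non-frozen components. All
density work is in log space (log-sum-exp), so far-tail points cannot
underflow to zero likelihood. Free-component SDs are floored at
1e-6 times the test-data range to prevent singular collapse onto a
single point.

Convergence: relative log-likelihood change below `tol` (default 1e-10)
or `max_iter` (default 500). Within a run the log-likelihood is
monitored and any decrease is logged as a warning (none is expected from
the update equations; the monitor guards against numerical regressions).

### Initialization

One free component per peak of the test histogram, plus the frozen
class 0. A peak is a maximal run of equal-count bins strictly exceeding
both flanking bins; a run touching the histogram boundary only needs to
exceed its single inner neighbor; an all-flat histogram has no peaks.
The histogram spans [min, max] of the test data with equal-width bins —
unpadded, since padding would only add empty flanking bins that cannot
create or destroy peaks. Peak center = run midpoint; initial component
SD = one bin width (scale-aware and deliberately wide — EM shrinks it);
initial weights equal across all components. A peak whose center lies
within one bin width of the reference mean is dropped as a duplicate of
class 0. These peak/plateau/boundary rules are this package's own
deterministic choices; any total rule that finds the same modes would
serve.

### Structural edits: vanishing and fusion

After each converged run, in this order:

1. **Vanishing** — every free component with expected support
   `n * weight < t_vanish` (default 2.0 values) is removed; weights are
   renormalized. Class 0 is exempt (frozen), with a logged warning when
   starved.
2. **Fusion** — while any adjacent pair satisfies
   `|mu_i − mu_j| < t_fuse * min(sigma_i, sigma_j)` (default t_fuse =
   1.0), the closest such pair is merged moment-matched (weight sum,
   combined mean and variance). If one member is class 0, the free
   member's weight is absorbed and class-0 mean/SD stay fixed.

If either edit changed the component set, EM re-runs, repeating until
stable. Removing starved components before fusing prevents a starving
component from dragging a healthy neighbor into a spurious merge; the
re-run-to-stability loop (rather than editing inside the iteration) keeps
each EM run a clean ascent. Both thresholds are exposed configuration.

### Model selection

The whole procedure runs once per histogram bin count in `bin_counts`
(default 10, 15, 20, 25, 30, 35, 40) and the fit with the lowest BIC
wins; ties break toward fewer classes, then the smaller bin count, making
selection deterministic. BIC = p·ln(n) − 2·ln L with n the test-sample
size and p = 3(G−1): G−1 free weights (normalization removes one degree
of freedom; w_0 counts as free because it is learned), plus mean and SD
for each of the G−1 non-frozen components. The frozen class-0 mean/SD
are constants supplied by the reference and are not counted. This
parameter-count convention is a documented package choice; BIC
comparisons are only ever made within one convention, so selection is
unaffected by the offset any alternative convention would add.

## Classification rules

Three consecutive rules, each a refinement of the previous:

1. **proba** — maximum a-posteriori class under the fitted mixture,
   using fitted weights as priors. Posterior ties resolve toward the
   label of smaller absolute value (conservative toward
   reference-like). When w_0 is close to null (< 0.01) the posterior of
   class 0 is essentially zero everywhere and proba classification of
   the reference cohort is flagged invalid.
2. **cutoff** — interval assignment at the *minimal-misclassification
   cutoff* between each adjacent class pair: the root of
   phi(x; mu_L, s_L) = phi(x; mu_R, s_R) strictly between the two means,
   i.e. the equal-weight crossing point (fitted weights deliberately not
   used, so a heavy class cannot push the boundary into a light
   neighbor's territory). With unequal SDs the log-density equality is a
   quadratic; the off-interval root is discarded. If neither root lies
   between the means (one component engulfed by a much wider one), the
   SD-weighted midpoint (mu_L s_R + mu_R s_L)/(s_L + s_R) is used with a
   warning. A value exactly on a cutoff goes to the side nearer class 0.
   The boundary separating class k−1 from k (k ≥ 1) is named `up-k`;
   mirrored below class 0, `down-k`.
3. **s.cutoff** (stringent) — identical to cutoff except the two
   class-0-adjacent boundaries move to the ends of their *tolerable
   intervals*: the boundary just above class 0 to its right end, the one
   just below to its left end. This widens the class-0 interval, so the
   reference-like class can only gain values, and classes not adjacent
   to class 0 keep identical counts.

**Tolerable interval.** With equal-weight total error
TotErr(c) = P(X > c | left) + P(X < c | right) (normal tails), the
interval (c_L, c_R) around the minimum c* collects the points where
TotErr = (1 + r_tol) · TotErr(c*), located by bracketed root search on
each side of c* and clamped at the two means under pathological overlap.
The relative-inflation parameterization r_tol (default 0.10) is this
package's formalization of "tolerable misclassification trade-off"; it
is dimensionless, symmetric in the two error kinds, and collapses to the
point cutoff at r_tol = 0. Because the published tool does not state its
interval formula, stringent-rule class fractions are comparable in
pattern but not digit-for-digit.

## Diagnostics

A multiclass labeling is dichotomized at a boundary (positive = class ≥
k, e.g. the `up-2` rule) and compared against a binary clinical truth.
From the 2×2 table: sensitivity, specificity, prevalence, PPV, NPV,
accuracy. Confidence intervals: exact Clopper–Pearson (inverse beta) for
the binomial proportions, standard logit intervals for the predictive
values — the conventions of the common online diagnostic-test
calculators. Predictive values at an assumed population prevalence p use
Bayes' rule:
ppv = se·p / (se·p + (1−sp)(1−p)), npv = sp(1−p) / ((1−se)p + sp(1−p)).
Degenerate denominators (e.g. PPV with no positive calls, or a boundary
proportion whose logit interval is undefined) are reported as missing
with a note rather than fabricated.

## Stability by resampling

A fraction (default 0.8) of the test and/or reference cohort is drawn
*without replacement* up to 100 times (hard cap, mirroring the original
interface); with-replacement draws are deliberately avoided because
repeated far-tail values can manufacture false classes. Each resample
re-runs the full selection pipeline (all bin counts, BIC choice) and
records the class count, class means, and the down-1/up-1/up-2 cutoffs;
when the reference is in scope its class-0 constraints are re-derived
per resample, matching the constraint's semantics. Classes are aligned
across resamples by signed label, with the class-count distribution
reported alongside so label alignment can be judged. Failures are
recorded per resample, never dropped, and everything is reproducible
from one seed.

## Synthetic data generator

`g3mix.synth` draws the test cohort from a specified mixture, the
reference from the designated reference component only, and queries from
the full mixture on independent RNG streams, returning
component-of-origin labels for recovery tests. `erbb2_like()` uses the
published 4-class ERBB2 mRNA parameterization — class 0: 40.4 ± 13.6
(weight 0.46), class 1: 88.7 ± 48.9 (0.38), class 2: 403 ± 189 (0.14),
class 3: 879 ± 29.1 (0.02) — with cohort sizes 142 test / 34 reference /
75 query, left-truncated at 0 by rejection since signal intensities are
nonnegative (for these parameters truncation touches only the far-left
tail of class 0/1).

What the generator does *not* emulate: assay noise structure (plate
effects, probe chemistry), left-censoring at detection limits, batch
differences between cohorts, and non-Gaussian skew within a class.
Passing recovery tests therefore show that the estimator inverts its own
generative model at realistic sizes — not that real assay data meet the
mixture-of-normals assumption.

## Numerical choices and edge cases

- Likelihoods, posteriors: log space throughout; posteriors never NaN
  for finite input.
- SD floor 1e-6 × data range; weights renormalized after every E/M,
  vanish and fuse step.
- Root finding: Brent's method at xtol 1e-12 for cutoff intervals;
  closed-form quadratic for the cutoff itself.
- Degenerate inputs: constant reference → hard error (no class-0 SD);
  single-class model → empty cutoff set with warning; cohorts shorter
  than `min_n` (default 5) rejected at read time.
- Boundary and posterior ties resolve toward class 0, preferring the
  "reference-like" call when the data cannot distinguish.
- Outputs are written at full double precision; console display rounds
  to 4 significant digits.

## Problem sizes used in the test suite

Simulation-based checks run at the sizes a desk validation needs, chosen
to keep sampling error well under the asserted tolerances: parameter
recovery at n = 2000, class-count selection over 50 replicate draws of
n = 500, rule-agreement at n = 5000, stability with ≤ 12 resamples of a
400-point cohort. The published cohort sizes (142/34/75) are used by the
`erbb2_like` fixture for end-to-end shape checks.

## Known limitations

- Univariate per-analyte modeling only; no multivariate extension, no
  cross-analyte covariance.
- BIC with few test values (n < ~50) is weakly informative; the class
  count then fluctuates across resamples, which the stability report is
  designed to expose.
- A narrow far-tail cluster of ≥ t_vanish expected values can
  legitimately win BIC as an extra class on reference-only data at
  moderate n; the stringent rule and the stability report are the
  intended guards.
- The published per-class sample fractions and BIC values depend on the
  original cohort measurements and are not reproducible from printed
  parameters alone.
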