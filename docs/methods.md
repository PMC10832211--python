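# Methods

## Model and assumptions

Growth of a healthy child from birth to roughly 36 months is modelled as a
saturating process: size `P` (weight in kg or height in cm) at age `Age`
(days) follows

    P(Age) = c1 + a1 · Age / (b1 + Age)

with child-specific parameters.  `c1` is the size at age 0 and empirically
tracks birth weight/length; `a1` is the asymptotic gain above birth size;
`b1` (days) the age at which half of that gain is attained.  The model is
deliberately simple — three parameters, monotone, concave — so that it
smooths noisy series without overfitting; it makes no claim about growth
after age three, saltatory short-term dynamics, or BMI.

The curve cannot represent linear growth: as a child's trajectory approaches
a straight line, the least-squares optimum pushes `a1, b1 → ∞` with
`a1/b1` tending to the slope.  This degeneracy is treated as an informative
failure mode, not an error.

## Fitting

Per-child unconstrained nonlinear least squares by Gauss–Newton:

- steps solve the linearised problem `J·Δ ≈ r` by least squares; a line
  search halves the step (up to `max_halvings`, default 10) while the SSE
  does not decrease;
- start values `(a1, b1, c1) = (5, 20, 2.5)` for weight, `(60, 530, 50)` for
  height; a "rescue" start `(15, 500, ·)` is available for series lacking a
  birth record, where the default start fails more often;
- convergence when the relative SSE improvement < `1e-10` or the relative
  parameter step < `1e-8` (`max_iterations` default 50); a stalled line
  search at a numerically stationary point (max |Jᵀr| ≤ 1e-8·max(1, ‖r‖))
  also counts as convergence;
- divergence (`diverged_unbounded`) when `|a1|` or `|b1|` exceeds
  `divergence_bound` (default 1e7 — far above any physiological value) or
  the SSE becomes non-finite; a rank-deficient Jacobian at huge parameters
  is classified the same way, since the two columns become collinear exactly
  in the linear-growth limit;
- `singular` for rank-deficient normal equations at ordinary parameter
  values and for convergence to a sign-degenerate optimum (`a1 ≤ 0` or
  `b1 ≤ 0`); no constraints are imposed during iteration;
- RMSE divides by n (no degrees-of-freedom correction), so with Gaussian
  noise σ and n points a converged fit has expected RMSE ≈ σ·√((n−3)/n)
  (≈ 0.17 kg at σ = 0.2 kg, n = 12).

Because the objective is non-convex, convergence is to a stationary point;
a dedicated test cross-checks the attained SSE against an independent
grid-plus-polish search on randomly sampled visit series.  Fitting requires
at least 3 distinct ages (the protocol itself requires ≥ 5 observations);
duplicate ages are allowed and all enter the SSE.

## Cleaning and visit assignment

Values beyond 1,125 days are dropped; weight values on days 2–19 are dropped
(post-natal weight loss) while the day-0/1 birth record is kept; subjects
with fewer than 5 remaining observations are excluded (an exclusion value,
not an error).  The implausibility screen is automated — heights that fall
more than 0.5 cm below an earlier maximum, and robust z-scores (median/MAD
of residuals from a centred running median of window 3, falling back to the
standard deviation when MAD degenerates) above 5 — and is advisory and off
by default, since a manual two-reviewer adjudication cannot be reproduced.

The 12 well-baby visit windows (closed day intervals) are: day 1, 20–44,
46–90, 95–148, 158–225, 250–298, 310–399, 410–490, 500–600, 640–800,
842–982, 1024–1125.  Within a window the measurement closest to the window
midpoint is assigned, ties to the earlier age; day-0 records qualify for
visit 1.

## Evaluation protocols

**Imputation study.**  Subjects with complete visits (7 = first year,
12 = all) are refitted after removing every combination of 1..5 visits; the
refit is scored against *all* of the subject's visit measurements, so the
cost of losing a visit appears as a positive mean ΔRMSE versus the
subject's own all-visit baseline.  (Scoring only the retained points would
let dropped visits *reduce* in-sample RMSE and could not rank visits by
importance.)  Combinations leaving < 3 points are reported degenerate;
refit failures are counted, not averaged.

**Holdout comparison.**  One uniformly random non-birth measurement per
subject is removed (per-subject RNG streams spawned from the experiment
seed, so the choice depends only on cohort and seed, never on the method
list); every registered method predicts it from the remainder, and the
per-subject one-point RMSE is its absolute error.  Subjects on which any
method fails are dropped from all methods, keeping the comparison paired.
Baselines: last observation carried forward, OLS line, LOESS (local
quadratic, tricube weights, span 0.75; small series fall back to the line
with a logged warning), and a cubic smoothing spline with GCV-chosen
penalty.  External growth models can be registered through the same
`(ages, values, age0) -> prediction` interface.

**Last-value prediction.**  Year windows are Y1 = days 0–365, Y2 = 366–730,
Y3 = 731–1125 (closed).  Eligibility: ≥ 5 points in Y1 and ≥ 2 in each of
Y2 and Y3.  The curve is fitted to Y1 only (scored on Y2–3), to Y1+Y2
(scored on Y3) and to all data (the baseline, scored on Y1–3, Y3 and Y2–3);
evaluation uses the subject's actual measurement ages.  Whether failed
restricted fits retry from the rescue start is a flag
(`rescue_on_failure`, default off).

**Summaries.**  Per-subject RMSE distributions are reported as mean, sd
(n−1), median, IQR (p75−p25), p90 and range; quantiles interpolate linearly
between order statistics.  The association between fitted `c1` and recorded
birth size is Spearman's rank correlation with average ranks for ties.

## Synthetic cohorts

The generator emulates the observational setting: per-sex parameter triples
with `a1`, `b1` log-normal (right-skewed, matched to median and IQR) and
`c1` normal, rank-coupled by a Gaussian copula at Spearman ρ ≈ 0.30 between
`c1` and each of `a1`, `b1` (the `a1`–`b1` coupling defaults to 0.50 —
larger total gain plausibly saturates later; neither a stated estimate nor
identifiable from the summaries matched, so it is a configurable package
choice).  Defaults, weight (kg): boys a1 median 14.1 IQR 5.77, b1 median
393 IQR 327, c1 mean 3.34 sd 0.58; girls 14.7/6.77, 499/425, 3.28/0.54.
Height (cm): boys 62.0/17.7, 502/266, 51.1/2.50; girls 64.5/19.6, 547/320,
50.3/2.40.  Visit ages are uniform integers inside each window (visit 1 =
day 1); visits drop out independently (default 0 — the protocols condition
on complete visits); measurement noise is homoscedastic Gaussian, default
0.2 kg / 1.0 cm, floored so values stay positive, with an optional
age-proportional inflation factor; a configurable fraction (default 1%) of
children are linear growers whose slope is set so their day-1095 size
matches a fresh draw from the curve cohort, assigned by a deterministic
exact-count rule that is stable as the cohort grows.  All randomness flows
from one seed through per-subject spawned streams, so enlarging a cohort
never reshuffles earlier subjects.

What the generator does **not** emulate: EMR-style irregular visit
frequency beyond Bernoulli dropout, demographic structure, correlated or
heavy-tailed measurement error, true joint parameter distributions (the
copula hits the reported rank correlations, nothing stronger), or
implausible-entry artefacts.  Passing tests therefore demonstrate
correctness of the machinery and behaviour under idealised noise, not
performance on real clinical data.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 200–500 subjects
per condition (1,000 fits for the per-sex recovery check, ~13,000 refits
for the 7-visit drop study at drop sizes ≤ 3), sizes at which the reported
rates and medians are stable to well within the tolerances asserted.  The
SSE cross-check uses 20 random 5–12-visit instances (visit 1 always
present, as the protocol requires) against an 80×80 log-spaced (a1, b1)
grid with `c1` profiled by linear least squares and a Nelder–Mead polish.
Quantile convention, year windows, tie-breaks and the divergence bound are
fixed as stated above and covered by tests.

## Known limitations

- The fitter is the plain Gauss–Newton reference procedure; series with no
  early (birth-anchor) measurement can stall it or fail outright — a
  property of the method, partly mitigated by the rescue start.
- Parameter uncertainties (standard errors, CIs) are not reported.
- External comparison models (mixed-effects, shape-invariant, spline-basis
  growth models) are supported only through the pluggable interpolator
  interface, not implemented.
- `a1` and `b1` have no direct physiological reading beyond shaping the
  curve; only `c1` maps onto an observable (birth size).
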