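# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter when results are compared
across implementations.

## Relative expression and trend smoothing

Per gene, expression is rescaled to `log2(CPM+1) / max(log2(CPM+1))`
over cells, giving a unitless profile in [0, 1] with the maximal cell
at exactly 1; an all-zero gene maps to the all-zero vector (0/0
convention). Normalization happens before smoothing, so trends of
genes with very different absolute expression are comparable on one
axis.

`LocalPolynomialTrend` is a loess-type smoother: at each evaluation
point the nearest `span` fraction of cells (default 0.75, the common R
default) is tricube-weighted and a local quadratic (`degree=2`) is
fitted by weighted least squares; the prediction is the local
intercept. Local quadratics reproduce any polynomial of degree ≤ 2
exactly, so noiseless linear trends are recovered at every span — a
useful sanity property the tests exercise. The smoother is linear in
the responses, y ↦ L y, so pointwise standard errors are
`σ·‖l(x)‖` with `σ²` estimated from training residuals on
`n − tr(L)` degrees of freedom; the 95% band is the normal
approximation fitted ± 1.96·SE. The test suite cross-checks fitted
values against R's `loess(..., degree=2, surface="direct")` on a
shared fixture (agreement ≈ 1e-10). Degenerate neighborhoods
(replicated abscissae) fall back to uniform weights over the tied
points, with a last-resort 1e-12 ridge for rank deficiency.

## Stage cutoff (T1 / T2)

The boundary between the early (stem-cell, GFAP-expressing) and late
(intermediate-progenitor, Tbr2-expressing) phases of the trajectory is
defined on the smoothed trend of the progenitor marker: its derivative
is taken by central finite differences on a 200-point grid; grid
points where the derivative changes sign or has magnitude ≤
`derivative_tol` (default `1e-4 · range(fitted) / grid_step`) are
stationary, and the cutoff is the rightmost stationary point followed
by a positive derivative — the last moment before the marker's final
rise. If the curve ends flat the last sign-change location is used;
a monotone trend raises an explicit `NoCutoffError` rather than
silently returning a boundary value. Cells with pseudotime exactly at
the cutoff are assigned T1 (≤ convention). On noiseless turning-point
shapes the detected cutoff is within one grid step of the truth.

Positivity defaults to CPM > 0; "positive for expression" has no
standard threshold, so the value is an explicit, recorded parameter.

## Fisher's exact test and odds ratio

The two-sided p-value follows the probability-mass rule: conditional
on the margins, sum the hypergeometric probabilities of all tables
whose point probability does not exceed the observed one. Weights are
exact integers (`math.comb`), so ties are resolved exactly and the
test suite can require equality with an independent enumeration oracle
to 1e-12 over every table with margins ≤ 30; scipy's implementation is
used as a second, independent cross-check. The odds ratio is the
cross-product ratio with conventions `(+,0) → ∞`, `(0,+) → 0`,
`(0,0) → 1`, making transposition-invariance and row-swap inversion
hold identically. Percentages are rounded half-away-from-zero to one
decimal; empty groups are reported as missing, never as 0%.

## Cell-cycle scores and cycling calls

A phase score is the sum of transformed expression over that phase's
marker genes present in the matrix (absent markers are dropped with a
warning; an error is raised only if a whole list is missing). The
default transform is log2(CPM+1), matching the trajectory stage; raw
CPM is selectable. Each raw score is divided by its across-cell
median, so the median cell scores 1 and normalization is idempotent.
If the median is 0 (sparse data), the mean of the strictly positive
scores is used instead; if every score is 0 the raw scores are left
unnormalized, with a warning either way.

The cycling rule — cycling iff max(norm G1/S, norm G2/M) ≥ 2.0 — is a
package construction: published scatterplots of the two scores do not
come with a printed decision boundary, so the threshold is a required,
logged parameter rather than a hidden constant. On simulated
populations whose cycling/noncycling marker means are separated ≥ 4×,
the default threshold recovers ground-truth labels with ≥ 99%
accuracy.

The bundled marker lists are the widely used consensus G1/S (43 genes)
and G2/M (54 genes) signatures mapped to mouse symbols by case
conversion, shipped as editable text files with a provenance header —
swap in your own lists via `MarkerSet` or a JSON file.

## Cumulative-labeling kinetics

The forward model is `LI(t) = min(GF·(Ts+t)/Tc, GF)`: the percent of
labeled cells rises linearly while unlabeled cycling cells keep
entering S phase, and saturates at the growth fraction once every
cycling cell has passed through S phase, at `t* = Tc − Ts`. The rise
intercept is `Li0 = GF·Ts/Tc`, the steady-state fraction of cells in S
phase.

The fit places a candidate breakpoint at each midpoint between
consecutive distinct sample times; points at or before the candidate
get an OLS line, points after it their mean (a zero-slope plateau),
and the candidate minimizing pooled SSE wins, ties to the smallest
breakpoint. Only splits whose rise slope is positive are candidates:
the model's rise is increasing by construction, and at realistic noise
an unconstrained search occasionally prefers a degenerate two-point
falling "rise" that no practitioner would accept. A timecourse with
no rising split anywhere raises `NoRiseError`. Continuity between the
two lines is deliberately not enforced — two independent lines are
fitted, and the reported `t_star` is their analytic intersection,
which need not coincide with the SSE split (both are reported).
Replicates enter as individual points, preserving degrees of freedom;
defaults `min_rise_points=3`, `min_plateau_points=2` leave the slope
one residual degree of freedom. Derived parameters require
`0 ≤ b ≤ GF` and m, GF > 0; the identities `Li0 = GF·Ts/Tc` and
`Tc − Ts = t*` then hold to rounding error.

Exact round-trip recovery (forward model → fit → parameters) on
noiseless 2-h sampling requires at least 3 sampled rise times and 2
plateau times, i.e. `Tc − Ts ≥ 5 h` under that design; the property
suite draws parameters under this identifiability constraint.

Uncertainty, when requested, comes from a nonparametric bootstrap that
resamples points with replacement within each sample time (preserving
the time design), with percentile intervals over successful refits.

### What the experimental design can resolve

At the emulated design — samples every 2 h from 2 to 24 h, duplicates
of ~200 cells, GF ≈ 16%, Tc ≈ 26.5 h, Ts ≈ 13 h — binomial counting
noise is 2.0–2.6 percentage points per sample, which propagates to a
relative standard error of roughly a third on the rise slope even when
the true breakpoint is known. Over 200 seeded simulations the median
absolute relative recovery error is about 5% for GF but ≈ 30% for Tc
and ≈ 45% for Ts; a 3-parameter continuous piecewise fit does no
better (the information is simply not in the data), so cell-cycle
lengths from a single timecourse of this size carry substantial
sampling uncertainty, and only order-of-magnitude contrasts between
conditions should be interpreted without replication. The acceptance
script reports these recovery errors as computed.

## Synthetic data

`simulate_trajectory` draws cells on an evenly spaced [0, 1]
pseudotime; per-gene mean trends are logistic sigmoids (monotone
shapes; rescaled so baseline and baseline+amplitude are attained
exactly at the endpoints) or a Gaussian bump (unimodal; negative
amplitude gives a dip-then-rise), since only smooth fitted curves, not
functional forms, are available to emulate. Noise is multiplicative
log-normal (`dispersion` = log-sd) plus Bernoulli dropout whose
per-cell probability is `dropout^(mean/max_mean)` — the configured
per-gene rate at the gene's maximal expression, rising toward 1 as the
local mean falls, emulating the inverse detection/abundance
relationship of single-cell data (dropout=0 disables zeroing,
dropout=1 zeroes everything). The default cast pairs a decreasing
MHC-I-like gene with static, increasing and late-rising markers at 140
cells, desk-scale for a small trajectory dataset.

`simulate_labeling` draws labeled counts Binomial(cells_per_sample,
LI(t)/100) per time and replicate; `cells_per_sample=None` is the
noiseless sentinel returning the expectation exactly. Defaults follow
the emulated experiment: wild-type-like (GF 16.3%, Tc 26.5 h, Ts
13.0 h), 2–24 h every 2 h, duplicates of 200 cells.

`simulate_cycling_population` gives two marker-positivity groups with
specified cycling fractions; cycling cells express the cycle markers
at 50× the noncycling mean, a separation chosen so that score-based
classification is essentially noiseless and association tests exercise
the tabulation, not the classifier.

What these generators do **not** emulate: read-level sequencing,
library-size variation (inputs are already CPM), gene–gene
correlation beyond the shared pseudotime, cell-type mixture structure,
or biological variability between experiments. Passing tests
therefore demonstrate correctness of the procedures under the stated
statistical structure, not robustness to every property of real data.

## Determinism and formats

Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); pipeline outputs embed the seed and a
SHA-256 hash of the resolved configuration, and repeated runs with the
same configuration are byte-identical. Readers validate rather than
coerce: duplicate ids, negative CPM, non-finite pseudotime and
malformed numerics are reported with the offending gene/cell or line
number. Expression values are written with 17 significant digits and
parsed with numpy's round-tripping strtod, so write→read is exact to
the last ulp.

## Known limitations

- The stage cutoff depends on the smoothing span; heavily smoothed
  trends shift the detected start-of-rise earlier. The span is a
  recorded parameter, not an inferred quantity.
- The cycling threshold is a convention; reported cycling percentages
  are only comparable under the same threshold and marker lists.
- Kinetics assume a single homogeneously cycling population with
  time-invariant parameters; quiescence exit, subpopulations and label
  dilution are out of scope.
- The section-count multiplier (×12) presumes a 1-in-12 systematic
  sampling series; counts are summed across sections by default
  (averaging is available where section counts are means per section).
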