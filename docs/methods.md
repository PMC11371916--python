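# Methods

## Model and scope

The package monitors time-between-events data assumed exponential:
`X_i ~ Exp(η)` independent, with the in-control scale `η0` either known or
estimated in Phase I by the mean of `m` waiting times.  A scale shift is
parametrized by `δ = η1/η0` (δ < 1: events arrive faster, e.g. an infection
outbreak; δ > 1: events slow down).  All monitoring happens on the
power-transformed observation `Y = X^(1/3.6)`, which is
`Weibull(η^(1/3.6), 3.6)` and close enough to symmetric that a two-sided
chart with symmetric limits is meaningful.  The exponent 1/3.6 is a fixed
constant of the method (`vsiewma.core.WEIBULL_SHAPE`), not a fitted
parameter; alternative symmetrizing transforms are out of scope, as are
subgrouped statistics (every sampling epoch draws a single observation).

## Run-length analysis

The EWMA statistic restricted to the action band `[lcl, ucl]` (normalized,
η̂0-free scale) is discretized into `2N + 1` equal subintervals;
transitions between subinterval midpoints follow the Weibull increment law,
giving a transient substochastic matrix `Q`.  Zero-state convention: the
chain starts at the state containing the in-control mean `μ0` (the central
state).  Expected absorption quantities come from one LU factorization of
`I − Q` applied to two right-hand sides:

* `CATS = b′(I − Q)⁻¹ h` — average time to signal, where `h` holds each
  state's sampling interval (`h1` for midpoints in the central region, `h2`
  in the warning region; a midpoint exactly on a warning limit counts as
  central);
* `CARL = b′(I − Q)⁻¹ 1` — average run length (samples);
* `CASI = CATS / CARL` — average interval per epoch (equivalently the
  visit-fraction-weighted mix `p1 h1 + p2 h2`).

The first interval of a run is the long one; the simulator follows the same
convention, so chain and simulation are directly comparable.

Estimated in-control scale: `γ = η̂0/η0 ~ Gamma(m, 1/m)` (mean 1, variance
`1/m`).  Unconditional metrics integrate the conditional ones against this
density with 64-node Gauss–Legendre quadrature on the central window
`[F⁻¹(1e-8), F⁻¹(1 − 1e-8)]`, renormalized by the window mass — the
integrand is smooth, so the quadrature error is far below the chain's
discretization error (doubling to 128 nodes moves AATS by < 0.1%).
`m = ∞` is an explicit sentinel (point mass at γ = 1), not a large finite
number.  AASI is the mixture of conditional CASI values, not the ratio
AATS/ARL; the two differ for finite `m`.

### Discretization accuracy

Defaults use `N = 100` (201 states), the resolution at which the published
reference values were produced; the package reproduces those values to
≤ 0.15%.  Users should know two quirks of this discretization:

* Because the interval vector flips a whole state between `h1` and `h2`
  whenever a warning limit crosses its midpoint, CATS does not converge
  monotonically in `N`: successive resolutions oscillate by about 1% before
  settling (at the reference design, in-control CATS is 370.3 at N = 100
  against ≈ 373.8 fully converged).  Calibrations performed at N = 100 are
  therefore N = 100 calibrations; this is the convention used throughout.
* The continuous-path Monte-Carlo simulator has no discretization error, so
  at 10⁵ replications (standard error ≈ 0.3%) it distinguishes the N = 100
  chain from the converged one.  The oracle-equivalence tests compare the
  simulator against the chain at N = 400, where the residual bias is well
  inside the simulation band.

## Design constraints and the warning-width solve

The optimizer (grids: λ 0.03–1.00 step 0.01; h1 from h0+0.1 to 2.5 step
0.1; h2 0.1–0.9 step 0.1; τ = 370.4, h0 = 1) pins `(K, W)` at each grid
point by `AATS0 = τ` and `AASI0 = h0`.  Two numerical points:

* The midpoint interval assignment makes AASI0 piecewise constant in `W`
  (steps of ~0.03 at N = 100), so that constraint is root-solved on the
  interval-overlap CASI — each state's interval weighted by the fraction of
  its subinterval inside the central region — which is continuous and
  strictly increasing in `W`, has the same continuum limit, and makes the
  solution exact and deterministic.  Reported CASI remains the
  visit-fraction definition; at a solved design the midpoint-rule AASI0
  differs from `h0` by at most one boundary state's visit share (~0.015).
* `W` is eliminated inside the `K` root-find: the in-control visit vector
  depends on `(λ, K)` only, both constraints are inner products with
  interval weights, so for each trial `K` the interval constraint is solved
  exactly in `W` and the time constraint becomes one-dimensional in `K`
  (bracket [1.2, 5]).  Visit vectors are cached per `K`; neighbouring grid
  points warm-start each other.  A fixed-interval grid point (`h1 = h2 =
  h0`) has a vacuous interval constraint: `K` is solved alone and `W` is
  returned as indeterminate (`nan`).

Ties in the objective within 1e-6 prefer smaller λ, then smaller h1, then
larger h2.  A coarse mode (λ step 0.05) serves quick sweeps.  δ = 1 is
rejected as an optimization target (no out-of-control objective).

### Known discrepancy in published warning widths

The published reference designs satisfy the time constraint precisely
(evaluating the N = 100 chain at the printed parameters returns
AATS0 ≈ 370.3 across all printed designs, Weibull and normal alike) but
cannot satisfy the interval constraint as stated: at the printed
`(λ, K)` for δ = 0.5, the in-control run length is 352.9 samples
independently of `W`, so `AATS0 = 370.4` and `AASI0 = 1` are mutually
exclusive for any per-epoch interval average obeying
`CATS = CASI × CARL`.  The printed `W` values are also non-monotone in `m`
where the design varies smoothly otherwise.  This package's solver honors
both printed constraints simultaneously, which yields slightly different
`(K, W)` (e.g. 2.666/0.607 versus printed 2.6426/0.6519 at λ = 0.09,
h = (2.0, 0.1)) and, at the optimum, a slightly smaller out-of-control
AATS1 at the same in-control AATS0.  Grid coordinates of the optimum
(λ*, h1*, h2*) are unaffected.  Published AATS1 values are reproduced by
evaluating at the printed parameters.

## Competitor charts

* Fixed-interval EWMA: the same chain with `h ≡ h0`; its comparison column
  is produced by its own one-constraint optimization over `(λ, K)` — this,
  not the variable-interval optimum's `(λ, K)`, reproduces the published
  companion values.
* Shewhart (λ = 1): geometric run length with closed-form
  `ARL = 1/p`; the discretized chain telescopes to the same number, which
  doubles as an exactness test.  The variable-interval Shewhart chart is the
  λ = 1 member of the EWMA family, solved by the same constraint machinery.
* Normal-assumption EWMA: identical discretization with the increment CDF
  swapped for a normal with the Weibull-matched moments.  Its designs meet
  the constraints under the normal law; re-evaluating them under the true
  Weibull law shows inflated in-control AATS (the reliability argument for
  the exact-Weibull chart).

## Monitoring runtime

Phase I: scale estimate = sample mean (positive data enforced).  Phase II:
absolute limits are the normalized ones times `η̂0^(1/3.6)`; zone
classification shares `zone_of` with the chain.  Default mode is
retrospective (`continue`): every point is scored and all alarms reported;
after an alarm the short interval is used (the operating rules only define
halting behaviour, and continuing cautiously is the conservative reading).
`halt` mode stops at the first alarm.  Time-varying early-sample limits
(variance factor `1 − (1−λ)^{2i}`) are available for retrospective display
via a flag; calibration and the chain always use the asymptotic limits.
The start value defaults to the in-control mean of the transformed
observation and is overridable.

## Synthetic data and what the tests show

The generator draws i.i.d. exponential waiting times (seeded), and the
run-length simulator replays the exact continuous recursion with
per-replication Phase I draws for finite `m` (γ sampled, limits
recomputed, then the run).  This emulates the model's own assumptions —
independence, exact exponentiality, a stable in-control scale — and none of
the features real surveillance data may add (autocorrelation, seasonal
intensity, censoring, aggregation).  Passing tests therefore certify the
computations and calibrations under the stated model, not robustness to
violations of it.  Monte-Carlo checks use 10⁵ replications for the oracle
sweep (standard error ~0.3%) and 3-standard-error acceptance bands;
distributional fixtures (mixture spread, false-alarm excess of unadjusted
designs) use a few hundred seeded draws, which suffices for the ordinal
claims they test.

## Limitations

* Calibrations are tied to the N = 100 convention (see discretization
  notes); a continuum-calibrated variant would shift `(K, W)` by ~1%.
* The gamma mixture assumes Phase I data are genuinely in control;
  contaminated Phase I samples are not modelled.
* One observation per epoch; subgrouped (gamma-distributed) statistics,
  one-sided variants, CUSUM competitors and raw-scale probability-limit
  Shewhart charts are out of scope.
* The full-grid optimizer is exact but exhaustive (~13k constrained solves;
  minutes per `(δ, m)` pair at `m = ∞`, substantially longer for finite
  `m`, where each constraint evaluation costs 64 chain solves).
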