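# Methods

## Model overview

`bedalloc` treats a hospital as a one-year fluid system: each department
admits patients at an annual rate, holds them for a Lomax-distributed stay,
and occupies beds in proportion to its accumulated patient-days. The package
chains four models:

1. **Lomax length of stay.** Stays follow a Lomax (Pareto type II) law with
   shape α > 0 and scale β > 0 days. The Lomax tail decays polynomially, so
   it represents the small number of very long stays that dominate bed
   pressure; the exponential distribution is the α → ∞ limit with the mean
   held fixed, which is why a large fitted α signals exponential-like data.
2. **Rate-derived parameters.** α and β come from two census rates, an
   admission-rate parameter p and a bed-stay parameter m, through
   α = (1−p)/(1−pm), β = (m−1)/(1−pm). The map is singular on pm = 1 and
   produces a valid distribution only for m > 1 when pm < 1; both conditions
   are checked and violations raise errors rather than returning NaN.
3. **Stay score and Needs.** ζ sums the Lomax density at whole days in
   [min_stay, max_stay] (defaults 5 and 365: sub-5-day stays do not count
   toward bed pressure, and the horizon is one year). The capacity-adjusted
   score is P(LOS) = ζ(1 + cap_fraction·beds) with cap_fraction = 0.1 — a
   10%-per-bed allowance that scales stay pressure with department size.
   Needs = (admissions/365)·P(LOS) − beds classifies departments into
   demand (> 0) and supply (< 0); whole-bed quotas are |Needs| truncated
   toward zero, and zero-quota departments drop out of the trade.
4. **Fuzzy-cost transportation and projection.** Moving a bed is priced by a
   triangular fuzzy number (5, min(D,S), max(D,S)) over the two departments'
   loads, defuzzified by (a+8b+c)/10; the unbalanced min-cost transportation
   problem is balanced with a zero-cost dummy line and solved exactly. The
   projected impact per department is New ALOS = Δbeds·365/⌊ALOS⌋, an
   admission change of patient_days/New ALOS, and new admissions = old +
   change. New ALOS is a turnover projection (annual bed-days gained spread
   over the old stay length), not a literal average stay; its sign tracks
   the direction of the capacity change.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_stay`, `max_stay` | 5, 365 days | summation window of the stay mass ζ |
| `cap_fraction` | 0.1 /bed | capacity allowance in P(LOS) |
| `rate_convention` | `reconstructed` | p = NA/(100·NS), m = NS/(100·OB); `literal` uses p = NA/NS, m = (OB/NS)·ALOS |
| `divisor_rule` | `truncate` | whole-day ALOS divisor in New ALOS; `full` uses exact ALOS |
| `cost_load` | `patient_days` | department load in the fuzzy cost (`alos`, `needs` available) |
| `tfn_floor` | 5 | left support of every cost triangle |
| `solver` | `modi` | `lp` re-solves via linprog (both reach the same optimum) |
| `redistribute_dummy` | off | give unshipped supply beds to the department with the largest projected admissions |

The `reconstructed` rate convention is the default because it is the unique
simple scaling that reproduces the printed p and m columns of the reference
census across all eight departments; the `literal` convention implements the
prose definitions verbatim and is retained for comparison. With loads =
patient-days the transport objective lands in the 10^5–10^6 range typical of
published figures; the load convention is configurable because the source
material does not pin it down.

## Numerical and convention choices

* **Exceedance exponent.** The survival function is (1+x/β)^(−α). A
  published worked example prints the exponent −(α+1) next to a value that
  only (1+x/β)^(−α) produces (0.0083 for x=10, α=2, β=1); the value, not
  the misprinted exponent, is authoritative here, and a regression test
  pins the distinction.
* **Discretization.** ζ sums the continuous density at integer days with no
  bin-integral correction — the sum is taken literally as specified.
* **Truncation conventions.** Occupancy percent is floored; quotas truncate
  toward zero (the unique simple rule reproducing the published totals
  113 = 35+22+39+17 and 53 = 31+9+1+12); Changes are truncated at 2
  decimals and new admissions at 1 decimal for display, while all stored
  values keep full precision so totals add up exactly.
* **New ALOS divisor.** The whole-day divisor reproduces seven of the eight
  published projection rows; the eighth (ICM, ALOS 1.8) was published with a
  one-decimal divisor of 1.7 — an isolated irregularity that is documented
  and regression-tested, not emulated. Departments whose ALOS truncates to
  zero fall back to the full-precision divisor with a warning.
* **Known inconsistencies in the reference census.** One department's (CD)
  printed Needs score cannot be derived from its own printed stay score
  (1.94 printed vs 0.43 computed), so pipelines fed the printed stay scores
  trade 52 demand beds, not the printed 53. The published derivation
  "p = 0.02, m = 50 gives α = 1.02, β = 49.02" sits exactly on the pm = 1
  singularity, where the parameter map is undefined; the package raises an
  error there. The published Shape/Scale census columns are not reproducible
  from the rate map and are not modelled.
* **Transportation solve.** MODI pivots choose the most negative reduced
  cost, breaking ties lexicographically by (row, column), so equal-cost
  optima are selected deterministically; degenerate bases are patched with
  zero-allocation cells chosen by a union-find spanning-tree rule. An
  iteration cap guards against cycling. Because the constraint matrix is
  totally unimodular, integral quotas always yield integral plans; the LP
  route asserts integrality after rounding at 1e−6. The dummy line costs
  zero, so its presence never changes the real-cell objective.
* **Goodness of fit.** MLE pins the location at 0 (stays live on [0, ∞));
  K-S p-values are plain, with no correction for estimated parameters —
  a caveat when n is small. AIC ranks families; BIC is reported alongside.

## The synthetic generator

`bedalloc.synth` emulates an annual census: per department it draws an
admission count, a Lomax stay law, and a target occupancy, then sets
patient-days as the rounded sum of simulated stays and beds from the
occupancy target. Under the derived parameter chain the stay mass ζ is
bounded near ~0.45 at census-typical magnitudes, which makes demand-side
departments (Needs > 0) possible only at high admission volumes; the
generator therefore engineers department 1 as a high-volume over-occupied
unit (9,000–13,000 admissions/yr, 2–5 day stays, occupancy above 1.05 —
think a large emergency or general-medicine service) and department 2 as a
long-stay under-occupied unit, guaranteeing both market sides by
construction. Remaining departments draw freely from the configured ranges
(800–5,000 admissions, shape 1.5–4, scale 2–12 days, occupancy 0.55–1.35),
magnitudes matching real annual department censuses.

What the generator does **not** emulate: arrival seasonality, queueing and
admission-refusal feedback, censored stays, transfers between departments,
or correlation between departments. Tests passing on synthetic tables
therefore demonstrate the pipeline's arithmetic and optimality properties
under the model's own assumptions, not forecasting skill on real hospital
data.

## Problem sizes used in tests

Solver optimality is verified against exhaustive enumeration on 200 seeded
instances up to 3×3 with quotas ≤ 4, and against the independent LP route on
larger random instances (up to 4×4, quotas ≤ 30); MLE recovery uses 10,000
draws per fit and 20 seeds for the bias-shrinkage check; Monte-Carlo checks
of the exceedance probability use 10^6 draws. These sizes make the full
suite run in a few seconds while keeping every statistical check at
comfortable power.

## Limitations

* The Lomax parameters derived from census rates are a modelling convention,
  not a fit: when raw stay samples exist, `fit_mle`/`gof_compare` should be
  preferred and the stay score computed from the fitted parameters.
* The fuzzy cost uses a single load convention per run; real transfer costs
  (staffing, equipment, distance) are out of scope.
* The projection chain is single-period and deterministic given the plan;
  it does not model uncertainty in next year's admissions.
* With the default conventions the transport objective's absolute value
  depends on the load convention; comparisons are meaningful within a
  convention, not across conventions.
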