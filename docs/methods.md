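# Methods

## Model structure

Each strategy is a cohort state-transition (Markov) model in quarterly
cycles (0.25 years).  An antibody arm has three mutually exclusive
states — on treatment with the monoclonal antibody, best supportive care
(BSC) after progression, and dead — with no return from BSC to
treatment; the BSC-only comparator has two states.  The cohort enters
with full mass in the first state at cycle 0 and transitions apply at
cycle boundaries: `occupancy[t+1] = occupancy[t] @ P`.  The lifetime
horizon is operationalized as "run until the alive mass falls below an
extinction tolerance (default 1e-9) or a cycle cap (default 200 cycles =
50 years), whichever comes first"; at the base-case probabilities the
cohort is extinct within ~50 cycles, so the cap never binds.

Base-case per-cycle probabilities: on treatment, 0.29 progression and
0.20 death (stay 0.51); in BSC, 0.36 death (stay 0.64).  The two
antibodies share transition probabilities (their trials showed
equivalent efficacy), so they differ only in cost; this makes the
equal-effectiveness dominance comparison exact by construction, and the
CEA layer treats effectiveness values within 1e-9 life-years as equal.

## Discounting and accrual conventions

Future costs and life-years are discounted at 5% per year, compounded
per cycle: the factor at cycle boundary *t* is (1.05)^(−0.25·t).  A
quantity defined at cycle boundaries (alive fraction, state cost load)
is accumulated under one of three conventions:

* `start` — boundary value opening each cycle, discounted at its time
  (∑ v(t)·d^t);
* `end` — boundary value closing each cycle, discounted at the cycle-end
  time (∑ v(t+1)·d^(t+1));
* `half_cycle` — the arithmetic mean of the two (trapezoidal half-cycle
  correction). **Default for both life-years and costs.**

The end-of-cycle discount exponent matters: discounting the closing
boundary at the opening time would shift the trapezoid and no longer
reproduce the published effectiveness values.  Under the defaults the
engine yields BSC 0.5548 LY (≈6.66 months), antibody arms 0.7713 LY,
increment 0.21655 LY — matching the published 0.55 / 0.77 / 0.22 and the
arithmetic behind the published ICERs (ICER × increment ≈ printed
incremental cost).

### Known residual gap on absolute costs

The original analysis was built in a commercial decision-tree package
whose cost-accrual setting is not published.  Working backwards from the
published arm costs, the implied discounted on-treatment accrual weight
is ≈1.353 cycles — between this engine's `end` (1.015) and `half_cycle`
(1.515) conventions — and no standard convention reproduces it.
Consequently, under the `half_cycle` default the antibody arm costs and
both ICERs come out ≈12% above the published figures (within the ±15%
the published inputs support), the incremental cost of cetuximab over
panitumumab ≈14.7% above, and the threshold-price reductions ≈4.5
(cetuximab) and ≈5.5 (panitumumab) percentage points above the published
≈60%/≈55%.  The BSC arm cost in isolation is closest to its published
value under the `start` convention (−6.7%).  All conventions are exposed
as configuration so the sensitivity of any conclusion to this choice can
be checked; the policy conclusions (both antibodies far above the
threshold, panitumumab dominant) hold under every convention.

## Cost construction

Drug cost per administration = ⌈total dose / vial size⌉ × vial price
(whole 100 mg vials, no sharing or wastage discount — forced by the
published cetuximab arithmetic: 875 mg → 9 vials → $1,500.30).  Total
dose is 500 mg/m² × 1.75 m² = 875 mg (cetuximab) or 6 mg/kg × 70 kg =
420 mg (panitumumab); administration is biweekly, 6 per quarterly cycle.
The on-treatment state cost adds routine care (outpatient, laboratory,
imaging, hospitalization) and the expected grade-3/4 adverse-event
hospitalization cost per cycle ($66.84 cetuximab, $63.34 panitumumab,
used as published aggregates; per-event unit costs, when supplied in a
custom configuration, replace the aggregate via Σ p·c).  The BSC state
costs $147.18 per cycle in every arm.  Monetary arithmetic runs at full
floating precision; rounding to cents is a reporting concern.

Cent-level inconsistencies in the published inputs are preserved as
metadata (`printed_*` fields) and never silently corrected: recomputed
panitumumab costs differ from the printed column by ≤$0.20 (5 × 270.43 =
1,352.15 vs printed 1,352.11; column total 8,442.82 vs component sum
8,442.64); the cetuximab and BSC columns reproduce exactly.  Dose
reductions (probability 0.18/0.175 per cycle) are carried as parameters
but scale drug cost only through an optional `dose_reduction_fraction`
multiplier, default 0 — the published quarterly drug costs equal
full-dose arithmetic, so dose reductions do not affect the base case.

## CEA layer

Strategies are sorted by ascending discounted cost.  Simple dominance:
another strategy costs no more and is at least as effective, with one
strict inequality (exact cost/effectiveness ties keep input order and
flag the later row, with a warning).  Extended dominance removes
frontier members whose ICER exceeds that of the next, more effective
member.  ICERs are reported along the frontier; each active arm's ICER
against BSC is additionally compared with the willingness-to-pay
threshold ($24,751/LY, stored as published even though 3 × 8,250 =
24,750) and reported as cost-effective or not, with the percentage
exceedance floored at zero.

## Sensitivity analysis

One-way analysis re-runs the entire pipeline (costs → Markov → ICER vs
BSC) at the low and high bound of one parameter, everything else at
baseline.  The eight published ranges are stored as printed (vial prices
varied down to zero; the other parameters ±25%, rounded as printed).
Parameters shared by both antibody arms (progression and on-treatment
death probabilities) are tracked on the panitumumab ICER — the
non-dominated arm — as set explicitly per range in the fixture; drug-
specific parameters track their own arm.  Body-surface and body-weight
perturbations re-trigger the vial ceiling and can therefore produce step
changes in the tornado, unlike the price search.

The threshold-price search bisects the vial price (vial count frozen at
its base-case value, which makes the ICER continuous and strictly
increasing in price) until the ICER against BSC is within $1/LY of the
threshold or 100 iterations — a relative tolerance of ~4e-5, far finer
than the 1% granularity at which reductions are reported.  Bisection is
implemented directly because the convergence contract is a tolerance on
the ICER value, not on the price.

## Synthetic survival data and calibration

The transition probabilities were originally fitted to trial survival
curves by log-linear regression; the curves themselves are not
machine-readable, so the calibration stage is exercised on synthetic
data.  The generator draws a cohort's exponential failure times from a
seeded generator (single integer seed, no global state) and reports the
surviving fraction at each requested time — binomial sampling noise
around S(t) = exp(−rt) — or the exact curve when `noiseless=True`.  The
exponential is the matched generative model: log-survival linear in time
is precisely the assumption of the log-linear fit, so exact recovery on
noiseless input (machine precision) and 3-standard-error recovery on
noisy input (n = 500) are the right correctness probes.  What the
generator deliberately does not emulate: censoring, non-constant
hazards, and Kaplan-Meier step structure; passing calibration tests
therefore demonstrates the fit and conversion machinery, not robustness
to real-world survival-curve pathologies.

The fit itself is ordinary least squares of ln S(t) on t *through the
origin* (S(0) = 1 by definition; a free intercept would imply otherwise
and bias short-horizon probabilities), unweighted, with zero-survival
points excluded (log undefined) under a warning.  The base-case pipeline
never runs calibration: the published per-cycle probabilities are used
directly, mirroring exactly what is and is not reproducible from the
published inputs.

## Numerical choices

* Transition-matrix rows stochastic within 1e-12; occupancy conservation
  within 1e-9; engine-vs-closed-form oracle agreement at 1e-10.
* Discount factors computed per boundary, never iteratively multiplied.
* Vial ceiling guarded against float-division landing on the wrong side
  of an integer.
* Effectiveness-equality tolerance 1e-9 LY; bisection tolerance $1/LY,
  ≤100 iterations.
* Degenerate inputs: survival constant at 1 fits rate 0 (R² defined as 1
  for the zero-residual fit); immediate-death cohorts produce a
  single-cycle trace; identity (immortal) matrices run to the cycle cap
  with `extinct=False`.

## Problem sizes

The base-case cohort is extinct within ~50 quarterly cycles; every
analysis (including the 16 pipeline runs of a tornado and the ~30
bisection steps of each threshold search) completes in well under a
second.  Synthetic-data tests use cohorts of 500–100,000 subjects,
chosen so binomial standard errors make the recovery assertions sharp.

## Limitations

* Life-years only; no utility weighting (as in the source analysis).
* No probabilistic sensitivity analysis; parameter uncertainty is
  explored only through the published one-way ranges.
* Constant per-cycle transition probabilities (exponential survival);
  no time-varying hazards or tunnel states.
* Cohort-level simulation only; no individual-level heterogeneity.
* The absolute-cost gap described above: effectiveness quantities are
  reproduced tightly, cost-side quantities carry the ≈12–15%
  accrual-convention uncertainty documented there.
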