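# Methods

## Model

Each athlete's absence history is a realization of a self-exciting point
process on the exposure clock of player hours (1 unit = 1,000 bouts).  The
conditional intensity is

    λ(t | H_t) = λ₀                                                   t ≤ T₁
               = λ₀ + a·b·(t − T₁)^(b−1) + Σ_{T_j < t} α·e^(−β(t − T_j))   t > T₁

with all five parameters strictly positive.  The first absence T₁ is a change
point: before it the process is a homogeneous Poisson process (so the time to
first absence is Exp(λ₀), with mean 1/λ₀ and window risk 1 − e^(−λ₀w));
after it a power-law wear-out trend (scale a, shape b; b > 1 gives an
increasing hazard) and an exponentially decaying excitation term (jump α per
event, decay rate β) are active.  Setting a = α = 0 recovers the Poisson
baseline, which the package represents separately with a single-parameter
model.

Assumptions: athletes are independent and identically distributed; absence
periods are short relative to play and are ignored on the exposure clock, so
back-to-back absences collapse to one event at a single player-hour mark (the
tie-merging rule); a retirement can be recorded as a final absence
("retirement-as-event"), which makes the career end coincide with the last
event and removes right-censoring from the likelihood.

## Likelihood and exposure end

Fitting maximizes the recursive (Ogata) form of the counting-process
log-likelihood; the direct form Σ log λ(t_j|·) − Λ(0, T) is kept as an
independent cross-check and the two agree to floating-point accuracy (the
test suite also checks both against adaptive quadrature of the intensity).
The recursion term R(j) = Σ_{k<j} e^(−β(t_j−t_k)) is evaluated in log space
(`logaddexp.accumulate`), so extreme β values explored by the optimizer never
overflow.

The integral term extends to the athlete's *exposure end*: the final event
under retirement-as-event, otherwise the censoring time (career_end).  The
latter is the correct censored-data likelihood and is what keeps parameter
recovery unbiased on horizon-censored synthetic cohorts; a zero-event
censored athlete contributes the pure survival term −λ₀·career_end.

## Optimization and uncertainty

* L-BFGS-B on log-parameters with box bounds (log scale [−12, 6]); e^(−12)
  acts as the zero boundary that the trend/excitation coordinates reach when
  the data carry no self-excitation.
* Multi-start: the first start is a moment-based guess (λ₀ = 1/mean first
  event time; a = α = 1; b = 2; β = 5), further starts jitter it
  log-uniformly within a factor of e.  The default is 8 starts; the test
  suite's replicate experiments use 1–4 starts, which the moment-based
  initialization makes sufficient on cohorts of the sizes used there.
* Standard errors: square roots of the diagonal of the inverse observed
  information, from a central finite-difference Hessian of the
  log-likelihood at the optimum (step max(1e−5, 1e−5·|θ|) per coordinate).
  When the observed information is not positive definite (typical for
  degenerate cohorts, e.g. one event per athlete) the SEs are reported as
  undefined with a warning rather than fabricated.
* Wald tests are two-sided z-tests against zero on the natural scale; AIC =
  2k − 2 log L, and two fits are called distinguishable only when their AICs
  differ by more than 10 units.

## Prediction

The next-absence probability within a window w freezes the history at the
prediction time t: p = 1 − exp(−Λ(t, t+w)) with no hypothetical events
inside the window adding excitation.  This equals the survival probability of
the first post-t event and slightly understates the probability of *at least
one* event in long windows; at tournament scale (w = 0.015) the difference is
far below the Monte-Carlo resolution of the calibration check.  An athlete
with no history uses the stage-I closed form regardless of t.

The team-level count of absent athletes is Poisson-binomial; its pmf is
computed by O(n²) iterative convolution, which is exact (the defining subset
sum is used as a test oracle up to n = 12), and its moments by Σp and
Σp(1−p).

## Simulation

Ogata thinning with a lookahead of 0.1 player hours per proposal window: on
(s, s+L] the intensity is dominated by λ₀ + trend(s+L) + α·A(s), since the
trend is nondecreasing for b ≥ 1 and the excitation A decays between events.
The bound is asserted at run time; b < 1 (a singular trend at the change
point) is rejected.  The excitation sum is maintained incrementally, so a
10,000-replicate horizon-1 experiment runs in about a second.

The rest-scenario simulator treats the rest itself as an absence starting at
`rest_start` (merged with an existing event at the same time under the tie
rule), lets the excitation decay through the blackout — during which no bouts
are played, hence no events — and counts simulated events on
(rest_end, eval_end].

## Synthetic cohorts

The generator shares the thinning engine and emulates a cohort of independent
careers.  Career models:

* `fixed_horizon` / `random_horizon` — careers censored at a fixed or
  Uniform(0.2, 1.6) exposure (the default staggered-career stand-in; no
  empirical career-length distribution is imposed), with
  `retirement_as_event = False`;
* `event_count_stop` — the k-th occurrence ends the career and is the
  retirement event.  Because this is a stopping time of the process, the
  completed inter-event durations remain exactly Exp(1) after time
  rescaling; the residual-uniformity tests therefore use this model.  Under
  horizon censoring the completed durations are conditioned on finishing
  before the horizon and are systematically slightly short — a real property
  of censored data, not an artifact — which a pooled KS test can detect at
  large sample sizes.

Division tiers for calibration are assigned by labelling the first fraction
(default 0.3) of each career lower-division (tournament window 0.007, else
0.015).

What the synthetic cohorts do *not* emulate: informative censoring (careers
ending *because* of injury), calendar seasonality, covariates (age, weight,
rank), and heterogeneity across athletes beyond the shared parameter vector.
Passing tests therefore demonstrate the correctness of the computations under
the model's own assumptions, not the model's adequacy for any particular real
cohort.

## Problem sizes and tolerances

Replicated experiments in the test suite use: 200 random micro-cohorts for
the likelihood cross-check (1e−6); 10,000 replicates for Monte-Carlo means
(±0.25 at t = 1.0); 1,000 stop-at-8 careers for per-path residual KS (≥ 98%
at the 1% level); ten 300-athlete cohorts for pooled-u uniformity (≥ 9 of 10
at the 5% level); a 1,200-athlete cohort for calibration (bins with ≥ 200
samples within 0.02 of the diagonal); a 500-athlete fixed-horizon-1.5 cohort
for parameter recovery (each parameter within 3 SEs); twenty 209-athlete
cohorts for the recovery-median check (< 25% relative error); and ten
200-athlete cohorts for the AIC model-selection direction (≥ 95%
`b_better`).  These sizes were chosen so the full suite completes in about a
minute while each check retains the power it needs.

## Known limitations

* The excitation kernel is exponential and unmarked; no covariates.
* Calibration evaluates tournaments on an exposure grid advancing by the
  tier window, not a real calendar.
* The frozen-history window probability is a (tight) lower bound for "at
  least one event in the window".
* Standard errors rely on asymptotic normality of the MLE; for small
  cohorts or parameters near the boundary they are unreliable, and the
  Wald test is then anti-conservative.
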