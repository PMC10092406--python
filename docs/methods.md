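# Methods

## Scope and data model

The package models what happens after a behavioural weight management
programme (BWMP) ends: how fast the intervention-minus-control weight
difference D(t) erodes ("regain"), what that does to quality of life, and
what it implies for lifetime health and spending when fed through a
multi-state lifetable. The unit of analysis is the *within-study
difference*: for each trial, intervention-arm mean weight change minus
control-arm mean change at each visit, re-clocked to months since programme
end (the point where contact intensity steps down). Working with
within-study differences over time makes the synthesis robust to
between-study differences in populations and measurement, at the cost of
saying nothing about absolute weight change.

Signs: weight change is negative for loss, so D(0) < 0 means the
intervention group is lighter at programme end and a positive slope of D is
regain. QoL is normalized at build time so higher is always better.

Arm differences are matched between control and intervention visits within
±0.5 month, because extraction tables report visit times at study level
with minor rounding. Studies with several intervention arms are pooled by
n-weighted average of arm means (variance propagated accordingly); a
"most intensive arm" alternative is available because the pooling rule is
genuinely open. Sampling variance of a difference is sd_i²/n_i + sd_c²/n_c
when both SDs are reported, and is left missing otherwise; downstream
fitters then fall back to n-based weights.

## Synthesis models

**Model 1 — random-intercept mixed model.** D_jt = β₀ + β₁·t + u_j + ε_jt
with u_j ~ N(0, τ²) per study and Var(ε_jt) = σ²/w_jt. Estimated by REML,
profiling β and σ², with the variance ratio φ = τ²/σ² optimized on a
bounded log scale; per-study block inverses use Sherman–Morrison so every
likelihood evaluation is O(number of points). Weights w: inverse sampling
variance when ≥80% of points carry variances (missing ones filled with the
median variance), else total analyzed n — trial plots conventionally size
points by participants, implying n-weighting when variances are
unavailable. Slope and intercept CIs are two-sided normal approximations
from the REML covariance. The implementation reproduces `statsmodels`
MixedLM (REML) to ~1e-6 on unweighted data, which the test suite checks.
Degenerate corner: with *exactly* noiseless data the residual variance
collapses and the REML criterion is unbounded in φ; the optimizer then
stops at the bound, the slope remains exact, and τ² is reported from the
boundary. Any realistic noise (≥1e-3 kg) restores regularity. If the
bounded search ever returns a non-finite criterion, a method-of-moments τ²
is used and a warning emitted.

**Model 2 — random-effects meta-regression.** One effect per study (the
final post-programme difference) regressed on its time since programme
end, with REML τ² and weights 1/(vᵢ + τ²). This deliberately discards the
interior visits, which is why it is expected to estimate a flatter slope
than model 1 on sparse late follow-up. The implementation matches R
`metafor::rma(..., method="REML")` on a frozen fixture to ≤1e-5.

**Model 3 — time to no-difference.** Each study contributes one
time-to-event observation: the first linearly interpolated time at which D
reaches zero between consecutive visits, censored at the last visit
otherwise. Interpolated rather than visit-snapped times are used because
visit grids are coarse (6–12 months) and snapping would bias the
Kaplan–Meier curve upward. The product-limit estimator itself comes from
`lifelines`; the median is the first time survival drops to ≤0.5 and is
reported as undefined when the curve never gets there.

**QoL.** Differences are standardized to SMDs with the pooled change-score
SD (no small-sample correction by default; the inflation is <1% at the arm
sizes generated here). Back-conversion to SF-36 points multiplies the SMD
by each study's SF-36 SD and summarizes with median and IQR. The
weight–QoL association reuses the model-1 machinery with the weight
difference as predictor.

**Publication-bias screen.** Meta-regression of the programme-end
difference on total follow-up length. The random-effects form is used
(rather than a fixed-effect weighted regression) because between-study
heterogeneity in programme-end differences is large; ignoring it would
shrink the CI and destroy nominal coverage, which the acceptance suite
checks against 93% over 500 null corpora.

## Trajectory and lifetable

The scenario trajectory is piecewise linear: D(t) = min(d0 + rate·t, 0)
("linear_regain") or D ≡ d0 ("no_regain"), with crossing time
t₀ = −d0/rate. During the programme itself the difference ramps linearly
from 0 at baseline to d0 at programme end (default month 6); this affects
only the first annual cycle. Weight converts to BMI statically,
ΔBMI = D/h², with age–sex heights. This replaces a dynamic energy-balance
treatment on purpose: the regain dynamics are already encoded in the
observed trajectories, so a second dynamic layer would double-count
adaptation.

The lifetable ages every 2017 sex × single-year-of-age cohort (18–100) in
annual cycles. Per disease, susceptible/case fractions follow explicit
annual (Euler) difference equations
C(y+1) = C(y) + i·(1−PIF)·S(y) − f·C(y), S(y+1) = S(y) − i·(1−PIF)·S(y);
prevalence among the disease-alive is C/(S+C) and the disease mortality
rate is f·C/(S+C). A step that would produce a negative state raises a
stability error rather than silently clipping. Intervention all-cause
mortality is reference mortality minus the summed disease-mortality
differences. Diseases are independent — no diabetes→cardiovascular
coupling.

The population impact fraction is computed on a continuous BMI grid
(10–60 kg/m², 0.1 steps, cell masses from lognormal CDF differences so
each stratum sums to 1 to machine precision):
PIF = 1 − ∫p′(b)RR(b)db / ∫p(b)RR(b)db, where p′ shifts the mass at
b ≥ 30 (the eligible population) by ΔBMI and RR(b) = rr^max(0, b−21). The
relative-risk factor is evaluated analytically at shifted abscissae, so
the only discretization error is in the density itself (first order in the
grid step; checked by refinement).

Person-years use the trapezoid of survivorship; utilities are the age–sex
baseline minus prevalence-weighted disease decrements, floored at 0 with a
warning. Costs: per-disease annual cost × prevalence, an other-cause
health cost per person-year (so longevity gains correctly carry costs),
and — in the health-and-social-care perspective — an old-age (85+)
social-care cost per person-year scaled by disability (1 − utility), so
prevention can save care costs even while adding life years. All flows are
discounted at 3.5%/yr to the baseline year, evaluated mid-cycle (y + 0.5).
Cohorts close at age 100; residual survivors accrue nothing further
(documented truncation).

## Economics

Per person *offered* (the BMI ≥ 30 adult population): Q = ΔQALY and
K = Δcosts (positive = savings). The price curve is C(λ) = λ·Q + K; C(0)
is the cost-saving price. ROI monetizes QALYs at £60,000 and is net return
per £1, (v·Q + K − C)/C, with a gross variant behind a flag since axis
conventions for ROI plots vary. Scaling results to other programme-end
losses multiplies Q and K by w_new/w_base (linear-benefits assumption).

## Uncertainty

Monte Carlo (default 5000 iterations) draws |d0| lognormally
(parameterized from its mean and a 95% interval; σ from the log-width, μ
set so the *mean* matches), relative risks and unit costs lognormally,
utility decrements normally, and keeps the regain rate fixed — start-point
uncertainty dominates because that is where the trial data are. Draws
violating invariants (e.g. RR < 1) are redrawn and counted. Intervals are
percentile-based because the outputs are strongly right-skewed. Each input
group gets its own RNG stream keyed by (seed, CRC32 of the group name), so
adding a group never perturbs another's draws and fixed seeds are bitwise
reproducible. The tornado evaluates each group at its 2.5th/97.5th
percentiles with the others central and ranks by spread. The reference
scenario's state simulation depends on no drawn quantity and is computed
once per pipeline, which is what keeps a full 5000-iteration run at full
population size to a few minutes on one CPU.

## Synthetic data: what it does and does not emulate

The corpus generator reproduces the *structure* the synthesis assumes:
study intercepts N(−2.8, 0.8²) kg, a common linear regain slope (default
0.027 kg/month), visit-level noise of 0.5 kg, programme lengths of 3–12
months, sparse follow-up at programme end +{6, 12, 24, 36, 60} months with
25% per-step dropout and a 60-month horizon, arm sizes 30–250, recoverable
variances, a low/unclear/high risk-of-bias mix of 23/53/24%, and a ~25%
QoL subset whose SMD tracks weight at −0.02 per kg. It does not emulate
nonlinear regain shapes, informative dropout, reporting errors, or
correlated multi-arm structures — so passing recovery tests demonstrate
estimator correctness under the stated model, not robustness to
misspecification. The toy epidemiology is a plausible, internally
consistent stand-in (Gompertz mortality, lognormal BMI with ~25% obesity,
four diseases with RR per BMI unit 1.03–1.15, UK-like cost magnitudes),
deliberately *not* calibrated to any national dataset; economic outputs on
it are structurally meaningful (orderings, affinity, reproducibility) but
their absolute levels are not estimates for any real population.

## Numerical choices and limitations

- REML searches are bounded scalar optimizations (Brent) on log-variance
  scales; tolerances 1e-8 (mixed) and 1e-10 (meta-regression).
- Annual Euler steps for disease states; closed-form three-state solutions
  exist but the annual-cycle convention was kept, with the stability guard
  and an equilibrium check (prevalence → i/f within 1% at long horizon)
  standing in for a step-halving analysis.
- The reference scenario holds baseline epidemiology and BMI distributions
  fixed over calendar time; no secular trends, no disease remission.
- Eligibility (BMI ≥ 30) enters only through the PIF mass shift and the
  per-person denominator; the ineligible population is carried unchanged.
- Multi-arm pooling, model-1 weighting, and the ROI definition are open
  design points; each default is stated above and the alternatives are
  exposed as flags.
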