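# Methods

## Overview

`hrpsim` simulates a regulated health-insurance payment system consisting of
(1) prospective risk equalization estimated on the full population, and (2) a
high-risk pool (HRP) that insurers fill prospectively using health-survey
information, compensated retrospectively on residual spending above a solved
threshold and financed by a flat contribution from the complementary group.
The pipeline is: generate population → rake the survey subsample to population
margins → fit the payment model and compute residuals → split survey responders
70/30 → train a residual-spending predictor on the training split → assign the
top X% of predicted residual spending in the test split to the pool → solve the
threshold, compensations and financing → evaluate subgroup profits/losses,
WMAR, and the Power reduction on the test split.

All evaluation happens on the held-out 30% test sample, mimicking an insurer
that trains on one contract period and applies the model to the next.

## Synthetic population

One person is a row of a pandas DataFrame with columns:

| column | meaning |
| --- | --- |
| `person_id` | integer id |
| `agesex`, `region`, `morbidity` | risk-adjuster classes (families configurable) |
| `spending` | annual spending, euro ≥ 0 |
| `died` | mortality proxy (raking margin) |
| `survey_responded` | person is in the survey sample |
| `cond_00` … `cond_22` | self-reported condition flags, present iff responded |
| `general_health` | `good` / `fair_poor`, present iff responded |
| `weight` | raking weight (NaN until raked) |
| `true_group_effect` | generator-only ground truth: expected residual under a correctly specified adjuster-only model |
| `spending_q` | population spending-quantile bin (added by the pipeline) |

Generating mechanism, per person *i*:

1. Adjuster classes are drawn per family from configured class probabilities;
   each class adds a euro effect to expected spending. Defaults: 10 age-sex
   cells spanning −900…+3500 euro, 4 regions with small effects, and a
   morbidity flag adding 2500 euro (structural, not calibrated, realism).
2. A latent severity factor `h_i ~ N(0,1)` is drawn. Its euro-scale effect on
   spending is `hidden_severity_sd · h_i` (default 750 euro), deliberately
   *absent* from the adjusters — this is exactly the residual signal an
   insurer can exploit.
3. Each of 23 condition flags is Bernoulli with logit `a_j + b_j·h_i`; the
   intercept `a_j` is solved by Gauss–Hermite quadrature + bisection so the
   marginal prevalence matches its target (default 8%, loading `b_j = 0.9`).
   A flag may also carry a direct euro effect on spending (default 0); the
   helper `with_group_undercompensation(cfg, j, delta, p)` uses this to build
   a group whose expected residual is exactly `delta` — the flag is made
   independent of `h` with prevalence `p` and effect `delta/(1−p)`, so the
   group mean exceeds the population mean (absorbed by the payment model's
   intercept) by `delta`. This is the parameter-recovery hook used by the
   tests and the acceptance script (`delta` = 500 euro, `p` = 0.2).
4. Expected spending is `max(base + adjuster effects + severity, floor)`,
   multiplied by 5 for decedents (`mortality_rate` 1%). Realized spending is
   zero-inflated lognormal: `B_i·L_i` with `B_i ~ Bernoulli(0.8)` and `L_i`
   lognormal with log-sd σ = 1.2 and location chosen so the unconditional mean
   equals expected spending. The closed-form mean makes oracle checks exact;
   σ = 1.2 and a 20% zero mass give the heavy right skew typical of annual
   claims.
5. Survey response is Bernoulli with logit `logit(survey_fraction) −
   nonresponse_beta·h_i` (defaults 0.30 and 0.35): sicker people respond
   less, so the raw survey is unrepresentative by construction.
6. `general_health` is `fair_poor` when `h_i` plus noise exceeds a cutoff
   (≈15% of the population), `good` otherwise.

`true_group_effect` is the realized severity minus its population mean; with
`hidden_severity_sd = 0` and no direct condition effects it is identically
zero, which is the null-control configuration: the survey then carries no
residual signal and no subgroup should be predictably mis-compensated.

What the generator does **not** emulate: real condition co-occurrence beyond a
single common factor (flags are independent given `h`), age truncation of the
survey frame, multi-year spending dynamics, insurer competition, and any
calibration to real administrative marginals. Passing tests therefore show
that the *mechanics and metrics* behave correctly under a plausible data
structure, not that euro magnitudes transfer to any real market.

## Raking

Survey weights are fit by iterative proportional fitting over the margin
variables (all adjuster families, the spending-quantile bin, and the mortality
proxy), in the fixed order listed in `RakingSpec` for determinism. Spending
bins are defined by population quantile cut-points (default 18); tied
cut-points (the zero mass) are collapsed deterministically with a warning.
Convergence: maximum relative error over all margins and classes below 1e-6
(default), at most 500 sweeps; non-convergence raises an error carrying the
worst margin. Weights are strictly positive, are normalized at the end to sum
to the population size, and are untrimmed by default (an optional cap exists
but is off). With a single margin variable IPF reduces to closed-form
post-stratification, which the tests use as an oracle.

## Risk equalization

Ordinary least squares of spending on adjuster-class dummies (one reference
class per family) with an intercept, estimated unweighted on the full
population — the administrative data are a census, so no survey weights enter
estimation. With an intercept, the mean residual on the estimation population
is zero to floating point (the model is zero-sum). Residuals for the survey
samples are computed from this same current-year fit; no prior-year model is
simulated. Empty classes or a rank-deficient design raise errors naming the
offending classes.

## Residual prediction

Features are the 23 condition flags plus the fair/poor general-health dummy —
no adjusters, since the target is residual spending, which is orthogonal to
the adjusters by construction (the feature set is configurable).

* `stepwise_linear`: forward selection; at each step add the feature with the
  lowest OLS AIC (`n·log(RSS/n) + 2k`), stop when no addition improves.
* `random_forest`: scikit-learn `RandomForestRegressor` with 100 trees and
  minimum leaf size 100; all other hyperparameters are library defaults and
  are recorded in the run manifest. Seeded, hence deterministic.

`top_fraction` selects `ceil(fraction·N)` persons by predicted residual, ties
broken by lowest person id (stable sort), so pools are nested across
fractions.

## Pool mechanics

The threshold solves `mean(e − s·max(e − τ, 0)) = 0` over members, with `e`
the member's residual (default) or actual spending and `s` the compensated
share (default 1). The retained mean is piecewise linear and non-decreasing in
τ, so bisection converges to the *smallest* root; the lower bracket starts at
`min(min(e), 0) − 1` and is widened geometrically if needed, because the root
lies below `min(e)` whenever all basis values are positive. Bisection runs to
a relative interval of 1e-12 (≤ 200 iterations) and the result is rejected if
the retained mean exceeds the 1e-6-euro solver tolerance. A pool whose mean
basis value is negative is infeasible (no τ can lift the retained mean to
zero) and raises a dedicated error. Compensation is never negative.

The threshold is solved per pool size on the evaluated (test) sample, and the
flat contribution is `total compensation / n_complement`, charged only to
non-members of that same sample — exact budget balance up to floating point
(the product `(total/n)·n` round-trips to ~1e-10 relative). Per-person revenue
is predicted spending + compensation (members) − flat contribution
(non-members); profit is revenue − spending.

## Evaluation metrics

Subgroup results use raking weights by default (unweighted mode available):
weighted mean profit `ē_g`, weighted SE `sqrt(Σw²(x−x̄)²)/Σw`, and a two-sided
t-test at 5% with `n_g − 1` degrees of freedom. Sign convention: positive
`mean_result` = profit = overcompensation. `WMAR = Σ N_g|ē_g| / Σ N_g` with
`N_g` the weighted group size; the four reported group sets are (1) no-chronic
plus the four "ever" conditions, (2) all subgroups, (3) yes/no chronic,
(4) general health.

Power reduction: every person's spending is inflated by 10% while pool
membership, τ and the flat contribution stay fixed (ex-ante quantities, and a
single insurer is small relative to the market); compensations are recomputed
and the metric is ΔΣrevenue / ΔΣspending ∈ [0, 1]. A `shock_scope="pool"` mode
shocks members only. A `recompute_financing=True` mode re-solves the flat
contribution after the shock; under strict budget neutrality the extra
compensation is then exactly clawed back and the metric is 0 — which is why
the fixed-financing reading is the default.

## Problem sizes and stochastic checks

The test suite and the acceptance script run on generated populations of
100k–200k persons (≈30% survey responders, test samples of ≈14k, pools of
≈140–690 members), chosen so the whole pipeline and its statistical checks
complete comfortably on a single CPU. Stochastic assertions use 3-SE (or
stated) bands around closed-form or ground-truth values. One consequence of
these pool sizes plus heavy-tailed residuals is that the solved threshold's
*pointwise* monotonicity in pool size is noisy even though its direction is
clear; the corresponding check asserts the top-1%→top-5% increase plus
pairwise monotonicity within a bootstrap band of τ's sampling noise.

## Known limitations

* The compensation basis defaults to residual spending; actual-spending
  compensation is implemented but the threshold then interacts with the
  payment model differently (well-compensated high spenders absorb funds).
* Baseline Power is taken as 1 (fully prospective model); payment models with
  spending-based adjusters would start below 1, which is out of scope.
* Financing by proportional payment reductions or profit repayment, regulator-
  assigned pools, and alternative learners (penalized regression, ensembles)
  are not implemented.
* Euro magnitudes produced on synthetic data are illustrative; only signs,
  orderings and the mechanics' identities are meaningful.
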