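# Methods

This note records the models the package implements, the defaults it ships,
the choices made where the design was genuinely open, and the limits of what
the synthetic-data tests demonstrate.

## Data model

Three record types carry the analysis:

* `BehaviorBout` — one timed occurrence of one of six activities, with a
  local-clock start and an integer duration in seconds. Bouts of one
  deployment may not overlap. Submerged-den occurrences are ingested as
  `sit_submerged`; basking and walking as `on_land`.
* `SamplingInterval` — one recording window (0.5 or 1.0 h; other positive
  exposures accepted with a warning) with its prey-attack count and a
  viability flag. This is the Poisson unit of analysis.
* `AttackRecord` — one prey-capture attempt with water position, hunting
  mode, habitat and a binary outcome (success = head-strike followed by
  inertial bites and swallowing). This is the binomial unit.

Diel bins are half-open clock intervals — morning [04:00, 09:00), day
[09:00, 18:00), evening [18:00, 22:00), night [22:00, 04:00) wrapping
midnight — so the four bins partition the 24-h clock exactly and a time on a
boundary belongs to the later bin. Clock times are local throughout; no
time-zone arithmetic is performed.

**Boundary-spanning bouts.** For duration-weighted budgets a bout that spans
a bin boundary is split proportionally (`split_bout_across_bins`, exact in
integer seconds), so each second of recording is credited to the bin it
occurred in. Point events (attacks) are assigned by their own timestamp. For
the randomization test a bout is instead assigned whole to its start-time
bin — see below.

## Attack-rate and capture-success models

Attack counts are Poisson with log link and offset `log(exposure_h)`;
coefficients are log-rates per hour. Outcomes are Bernoulli with logit link.
Fixed-effect fits use iteratively reweighted least squares (statsmodels)
with the convergence tolerance tightened to 1e-12 so the closed-form
identities (intercept-only rate = total attacks / total exposure;
intercept-only success = successes / trials; halving exposures exactly
doubles the fitted rate) hold to near machine precision and are asserted in
the tests.

Cell predictions are formed on the link scale as `x₀ᵀβ̂ ± 1.96·SE` with
`SE² = x₀ᵀ Cov(β̂) x₀`, then back-transformed (Wald 95% intervals). For
saturated categorical models the cell means equal observed proportions.
Boundary cells (0 or 1) and suspected complete separation are reported as
warnings on the fit object — transparency is preferred over silent
penalization or refitting.

**Random individual intercepts.** `u_j ~ Normal(0, σ²)` on the linear
predictor is integrated out with 25-node Gauss–Hermite quadrature and the
marginal likelihood maximized over `(β, log σ)` with BFGS. The parameter
count is the number of fixed effects plus one (σ). Twenty-five nodes are
ample for a single scalar random effect; the quadrature is verified against
brute-force numerical integration, and the full fit against an independent
adaptive-quadrature GLMM implementation (lme4, 25 nodes) in the test suite.
A caveat for AIC tables that mix both estimator families: the marginal
likelihood of a mixed model and the likelihood of a fixed-effect GLM are
different objects, and comparing their AICs follows the original analysis
convention rather than strict theory. Mixed-model cell predictions are
population-level (u = 0).

**Model selection.** AIC = 2k − 2 lnL, tabulated ascending with deltas; ties
break toward fewer parameters; a failed candidate is recorded in its row
with the error message rather than aborting the selection.

**Outlier rule.** Intervals with more than `threshold` attacks (default 10)
are flagged and excluded from rate fitting; the threshold is a parameter
because the rule exists to catch a qualitatively different process (a
feeding frenzy — many strikes into one prey aggregation) rather than a
fixed count. Flagged intervals are returned and logged, never silently
dropped, and their attack records remain in the success analysis, where the
unit of interest is the individual attempt.

## Randomization test for diel dependence of the budget

Null hypothesis: time allocation to each activity is independent of diel
bin. Per activity, all observed bout durations are pooled across bins and
individuals (`DurationPool`). Holding the observed bout count n(activity,
bin) of every cell fixed, each of R replicates (default 10,000) redraws each
cell's durations with replacement from its activity's pool and recomputes,
within each bin, each activity's share of the replicate's own total bin time
(so each replicate is a proper composition). The two-sided p-value for a
cell is the fraction of replicates whose absolute deviation from the null
median is at least the observed deviation — inclusive comparison, divided by
R with no +1 correction, so p = 0 is representable. Mathematical ties in the
deviation comparison are honoured with a 1e-12 relative tolerance.
Significance is declared at α = 0.05 and no multiple-testing correction is
applied across the 24 cells.

Design choices that were genuinely open:

* Pools are per-activity (six pools), not one global pool; a global-pool
  variant is exposed via `pool_scope="global"` for sensitivity analysis.
* Counts are held fixed at observed values; only durations are resampled.
* Replicate proportions renormalize by the replicate's own bin total, not
  the observed total.
* For this test a bout counts whole in its start-time bin, so the observed
  statistic is built from the same kind of whole-duration sums as the null
  replicates; splitting boundary bouts would make the observation
  structurally smoother than any replicate.

**What the test can and cannot detect.** Because per-cell counts are fixed,
the null and the observation share any count-driven share shift; the test is
sensitive to cells whose *durations* are atypical for their activity (e.g.
day-time submerged swims running much longer than submerged swims overall),
not to changes in bout frequency alone. The power test exercises exactly
that signal via the generator's per-bin log-duration shift option.

**Calibration.** The test is conservative by construction. Each observed
cell is a without-replacement subset of the very pool the null resamples
with replacement, with sampling fraction f equal to the bin's share of the
activity's bouts; the finite-population effect deflates the observed
deviation by about √(1−f) relative to replicates, giving per-cell type-I
error near `P(|Z| > 1.96/√(1−f))` ≈ 0.013–0.032 for the f ∈ [0.17, 0.38]
that any 24-h-covering design produces, rather than the nominal 0.05. The
fixed length of real recording windows (a deployment's bout durations sum
to the window) depresses it further. Measured under a bin-independent
generator: pooled rejection ≈ 0.024–0.029 at α = 0.05. The unit suite
therefore asserts validity (rejection never above the nominal band's upper
edge) and power, not exact attainment of the nominal level; exact
calibration would require reallocating observed durations without
replacement (a true permutation), which is deliberately not what this
procedure does.

## Synthetic deployment generator

The generator emulates the reference study design and doubles as the
package's test bed. Defaults: 15 individuals split 9/6 across two
site/years; 9 deployments of 7 one-hour intervals and 6 of 13 half-hour
intervals (102.0 potential hours; the 30/60-min split of the original
schedule is unreported, so this is a documented assumption); per-interval
viability Bernoulli(0.69); baseline rate 0.49 attacks/hour; diel rate
multipliers 1.1/0.45/0.7/1.9 (morning/day/evening/night), ordered
night > morning > evening > day and exposure-weighted to ~1 over the clock
so the marginal rate stays at the base; individual heterogeneity as normal
random intercepts on the log rate, sd 0.3 (an invented, configurable
default); success probabilities 0.68/0.47/0.34/0.34 by bin and 0.76/0.41 by
water position, combined additively on the logit scale against a 0.53
anchor — when only one factor is configured the cell probabilities are
reproduced exactly; covariate marginals: submerged 0.30, sit-and-wait 0.67,
vegetation 0.36.

Activity bouts form an alternating-renewal sequence: the next activity is
drawn with probability proportional to its time weight divided by its mean
duration (so long-run time shares converge to the weights), the duration
from a per-activity lognormal. Default weights are the six-category budget
0.414/0.369/0.096/0.059/0.059/0.007; these printed shares sum to 100.4%
because of rounding, so configuration accepts weight vectors within 0.5% of
unit sum and renormalizes exactly (the effective sit-at-surface weight is
0.4124). Duration parameters (log-seconds mean, sd): resting bouts ~10–20
min, swims ~2–3 min, foraging ~40 s — no duration distributions were
available to anchor these, so they are stated assumptions, configurable per
activity, with optional per-bin log-mean shifts for injecting diel duration
signals. The final bout of each window is truncated so bouts tile the
window exactly; a `feeding_frenzy` flag replaces one viable interval's
count with 18 to exercise the outlier rule.

All randomness derives from one integer seed fanned out to named substreams
(bouts / intercepts / intervals / attacks), so bout and attack processes
are independently reproducible and identical (config, seed) pairs are
byte-identical on disk.

**What passing tests do not show.** The generator draws bouts independently
given the current bin and tiles ideal windows; real deployments have
autocorrelated behavior, irregular viability (whole cameras failing rather
than random intervals), per-individual budgets, and attack covariates
correlated with each other and with activity state. Parameter-recovery
results therefore demonstrate correctness of the estimators under the
assumed model, not robustness to these realisms.

## Problem sizes

Recovery checks run at sizes chosen to make Monte-Carlo error small
relative to the quantities checked: 2,500 one-hour intervals for the
baseline rate (3 SE ≈ 0.042 attacks/h), ~12,000 exposure-hours yielding
≥ 5,000 attacks for the success cells (3 SE ≈ 0.03), ~750 recording hours
yielding ≥ 5,000 bouts for the budget (3 SE ≈ 2.7 percentage points), and
200 simulated studies for unbiasedness and calibration summaries. All
tolerances were fixed from these calculations in advance of running.
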