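# Methods

## The model

`esmvar` estimates a two-level Bayesian lag-1 vector autoregression
("dynamic structural equation model") for intensive longitudinal data from
experience-sampling (ESM) studies. For person *i* on an equally spaced
one-hour grid *t*:

    y_it = mu_i + gamma * h_it + w_it          (latent-mean decomposition)
    w_it = Phi_i w_{i,t-1} + eps_it,           eps_it ~ N(0, Sigma_w)

* `y_it` — K momentary composites (Likert units), observed only at grid
  cells occupied by a completed prompt;
* `mu_i` — latent person means (avoiding the bias of observed-mean
  centering);
* `h_it` — clock hour of the cell, centered at the grand mean over occupied
  cells; `gamma` detrends diurnal level shifts, as a control for
  non-stationarity over the day;
* `Phi_i` — person-specific K×K lag matrix: diagonal entries are
  autoregressive ("inertia") effects, off-diagonals cross-lagged
  ("spill-over") effects, all defined on a one-hour time step;
* `Sigma_w` — innovation covariance, common across persons, free
  off-diagonals (contemporaneous residual correlations).

At the between level the stacked random effects
`eta_i = (mu_i, vec(Phi_i))` — K + K² of them (6 for the two-variable
model, 12 for the three-variable model) — are jointly multivariate normal
with the two observed negative-schema scores (negative-self,
negative-other), with free covariance `Omega`. The schema blocks of `Omega`
yield the between-person correlations between schemas and dynamics. Gender
can enter as a between-level mean predictor of the random effects
(moderation).

### Where the hour term lives

The hour covariate is placed in the decomposition equation rather than
inside the latent recursion. The two parameterizations describe nearly the
same data features, but a recursion-level drift accumulates through
`(I - Phi_i)^{-1}` across the ~11 consecutive empty night cells of an ESM
grid, making the person means and the hour slope nearly collinear: in
study-scale simulations, hour-slope perturbations of ±0.002 moved the
posterior of the means by ±0.3 Likert units. The detrending form keeps the
means identified from the person-level data and the hour slope identified
from within-day variation, and is consistent with treating the hour of
measurement as a fixed-effect control.

## Estimation

All full conditionals are conjugate, so the sampler is a blocked Gibbs
scheme (the estimand is the posterior, not the update order):

1. **Missing cells.** Occupied cells pin the latent state exactly
   (`w = y - mu_i - gamma h`), so the missing runs between two anchors are
   conditionally independent Gaussian bridges; they are drawn exactly by
   forward filtering / backward sampling. The per-step smoother gains
   depend only on (`Phi_i`, `Sigma_w`) and the distance from the left
   anchor, so they are precomputed per person per sweep (batched) and the
   per-cell pass is a compiled kernel. Missingness is assumed MAR and all
   imputation happens inside the sampler.
2. **Person effects.** `vec(Phi_i)` given `mu_i` is a Kronecker-structured
   normal regression; `mu_i` given `Phi_i` is a normal update whose design
   per transition depends on which of the two cells is observed. Both use
   the conditional prior implied by `Omega` given the person's schema
   scores (and gender, if modelled).
3. **`Sigma_w`, `Omega`** — inverse-Wishart updates.
4. **`gamma`, fixed effects, gender coefficients** — normal updates.

Priors are diffuse: normal(0, 10^6) on all mean-type parameters,
inverse-Wishart(identity, K+1) on `Sigma_w`, inverse-Wishart(identity,
d+1) on `Omega` (d = random effects + schema covariates). These are
documented stand-ins for "default non-informative priors" in the original
software; burn-in (first 50% of each chain, not stated in the source
analysis) precedes thinning. Two sampler profiles ship: the full profile
(4 chains × 5000 iterations, thinning 10) and a smoke profile
(2 × 500, thinning 5) used in simulation studies and tests.

With `random_effects=False` the model collapses to a single pooled VAR(1)
with flat priors; on complete data its posterior mean reproduces the
stacked least-squares lag regression to Monte-Carlo accuracy, which the
test suite uses as an estimation oracle.

Diagnostics: split-chain potential scale reduction and effective sample
size (via arviz) for all fixed effects, residual and between-level
(co)variances; the report flags any parameter above the threshold
(default 1.1).

## Post-processing

* **Within-person standardization.** Per draw and person the stationary
  covariance `V_i` solves the discrete Lyapunov equation
  `V = Phi_i V Phi_i' + Sigma_w` (vec form, Kronecker inverse — K ≤ 3 keeps
  this exact and cheap); each lag coefficient is scaled by
  `sd(predictor)/sd(outcome)`, averaged over persons within the draw, then
  summarized across draws (median, equal-tailed 95% CrI). Draws with a
  non-stationary `Phi_i` are excluded from that draw's average and counted.
  Means are reported on the raw 1–7 scale, matching the magnitudes a reader
  expects from such tables.
* **R².** Per draw and person, `R2_k = 1 - Sigma_w[kk] / (V_i + var(h)
  gamma gamma')[kk]`: the share of stationary within-person variance
  explained by the lagged predictors and the diurnal trend; averaged over
  persons. The trend share is included in R² but excluded from
  standardization; both choices are configurable.
* **Intervals and significance.** Equal-tailed empirical quantiles; point
  estimate = posterior median; an effect is flagged iff the 95% CrI
  excludes zero. At least 100 retained draws are required.
* **Schema correlations.** Per draw, `corr = Omega[j, s] /
  sqrt(Omega[jj] Omega[ss])` from the covariate blocks; 24 cells
  (12 effects × 2 schemas) for the three-variable model.

## The synthetic study generator

The generator emulates a six-day signal-contingent ESM study of momentary
social anxiety, paranoia and loneliness in a non-clinical young-adult
sample, with known ground truth for every stage:

* **Schedule** — 10 prompts/day in equal-width blocks of a 13-hour waking
  window (waking start 09:00), one uniform draw per block, whole-day
  rejection until consecutive gaps ≥ 15 min.
* **Persons** — `(mu_i, vec(Phi_i), schemas)` jointly normal; defaults:
  grand means ≈ 1.9–2.0, autoregressions 0.31–0.61, positive cross-lags
  0.05–0.26 (one-hour step), mean variances 0.72–0.95, schema coupling with
  the correlation pattern described above (strong positive with all means;
  negative-self with the paranoia→social-anxiety path; negative-other
  positive with social-anxiety→paranoia, negative with
  loneliness→paranoia). Schema scores: mean 6, SD 4, inter-schema r = 0.5.
* **Stationarity calibration.** Lag-coefficient dispersions are set so the
  joint-normal person model is almost entirely stationary (SDs 0.07–0.18;
  rejection rate ≈ 5% at the spectral-radius bound 0.95). Larger
  dispersions would contradict the within-person stationarity the model
  assumes: they put roughly half the normal mass on explosive dynamics,
  and the rejection step then produces a strongly skewed person population
  that no normal random-effects model can represent. The bound sits at
  0.95 rather than 1 because near-unit-root persons imply stationary SDs
  of tens of Likert units — impossible for a bounded response scale — and
  single such persons otherwise dominate a whole simulated sample.
  Because rejection slightly shifts the realized population, the
  generator's documented ground truth is the *effective* (post-rejection)
  mean, estimated by a large Monte-Carlo draw from the same generator.
* **Series** — the latent process runs on the continuous one-hour grid
  through nights, started from its stationary distribution; a prompt
  observes `mu_i + gamma h + w` at its nearest grid cell (two prompts
  within the same hour legitimately share a cell). Composites are item
  means; by default they are continuous Gaussian values (`likert_emulation`
  clips to [1, 7], and optional item emission rounds integer item
  responses) — recovery properties are defined under the model's own
  distributional assumptions, and the clipping/rounding path exists to
  study floor effects separately.
* **Compliance** — per-person completion probabilities Beta-matched to
  mean 0.721, SD 0.16; prompts thinned by independent Bernoulli draws that
  never inspect responses (MAR by construction). Hour-trend truth defaults
  to −0.02 Likert/h, a mild diurnal decline.

## Design rules and the time grid

Persons completing fewer than one-third of their scheduled prompts are
excluded (strict comparison: exactly one-third is retained, matching a
cutoff of 20 of 60). Observations are assigned to a one-hour grid anchored
at each person's first completed prompt (`cell = round(elapsed / 60)`,
ties to even); the grid runs continuously across nights, which appear as
runs of missing cells so that overnight carry-over attenuates through
missing steps rather than restarting per day. Collisions keep the earlier
observation, shift the later one to the next cell if free, else drop it —
all logged. The hour covariate of a cell is the clock hour of its nominal
time.

## Problem sizes in the shipped checks

The simulation studies in the test suite and acceptance script run at the
study's design scale (134 persons, 60 scheduled prompts, ~72% compliance)
with the smoke sampler, 20 replicates for the recovery/coverage suite and
5 for the acceptance script's bias summary; generator-level Monte-Carlo
checks use 20,000-person draws. These sizes give Monte-Carlo error well
inside the asserted tolerances while keeping a full run in minutes.

## What the generator does not emulate

Non-response is independent Bernoulli per prompt given the person's
completion probability. Real ESM compliance is streakier (whole sessions
or days missed, expiry effects), which shows up in one descriptive: with
independent thinning at 72% compliance the mean gap between consecutive
*completed* within-day prompts is ~104 min (scheduled gaps of ~78 min
divided by the completion rate), whereas streaky missingness leaves the
typical completed-to-completed gap near the scheduled spacing. Passing
tests therefore demonstrate correctness under MAR with independent
prompt-level missingness, not robustness to structured non-response.
Likewise the generator omits response latency within the 15-minute expiry
window (observed time equals scheduled time) and models only the two
schema scores and gender at baseline.

## Known limitations

* Likert responses are treated as continuous Gaussian (as in the source
  analysis); no ordinal measurement model.
* `Sigma_w` is common across persons (person-specific residual variances
  are not implemented).
* Lag order is fixed at 1; effects are defined on the one-hour grid, so
  dynamics at shorter or longer time scales are aliased.
* No model comparison / information criteria.
* The hour trend is linear in clock hour; periodic or categorical trends
  would need a different covariate column.
* Posterior means of fixed effects at this design's information level
  (≈20 usable transitions per person) carry a small finite-sample
  attenuation on the autoregressive diagonal, visible only when per-person
  series are short and pooling is weak; it shrinks with series length and
  is well inside the recovery tolerances at the study's scale.
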