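# Methods and design notes

## Estimand and model

Reliability of naming speed is defined as the correlation of by-participant
latent speed effects across two halves of the data: even vs. odd trials or
first vs. second half within a session (split-half), session 1 vs. session 2
(test-retest), or non-speeded vs. speeded task (cross-condition). The model
is a bivariate hierarchical regression of log-latencies with *no global
intercept*: each half gets its own fixed intercept μ_h and its own
by-participant adjustment b_ih, plus a single by-item intercept g_j and
residual σ. The parameter of interest is ρ = corr(b_i1, b_i2). A Pearson
correlation of per-participant mean latencies is attenuated by trial and
item noise; the hierarchical ρ is the correlation of the underlying effects
themselves.

Priors (log-ms scale): μ_h ~ Normal(6.75, 1.5) — the prior median latency is
exp(6.75) ≈ 854 ms, and ±1 prior SD spans ≈ [191, 3828] ms, a weakly
informative range for naming; τ_1, τ_2, σ_item, σ ~ half-Normal(0, 1);
ρ ~ LKJ(η = 2), i.e. density ∝ (1 − ρ²), which mildly downweights |ρ| ≈ 1.
The likelihood family is Normal on the log scale (lognormal latencies);
this is the natural reading of priors stated on the log scale, and naming
latencies are strictly positive and right-skewed. Credible intervals are
equal-tailed 95% quantile intervals throughout.

## Computation

No probabilistic-programming backend is used. The latent effects
u = (b, g) are jointly Gaussian, so they are marginalized analytically:
with y = Xμ + Uu + ε and D = Cov(u), the marginal covariance is
V = σ²I + U D U′ and the Woodbury identity gives

    log|V| = N log σ² + log|D| + log|M|,  M = D⁻¹ + U′U/σ²
    r′V⁻¹r = (r′r − (U′r)′ M⁻¹ (U′r)/σ²)/σ²

U′U, U′X, U′y, X′X, X′y, y′y are accumulated once per data set, so each
likelihood evaluation costs one Cholesky factorization of the
(2P + I) × (2P + I) capacitance matrix M (≈ 400 × 400 at the default study
size) — a few milliseconds. The 7 hyperparameters (μ_1, μ_2, log τ_1,
log τ_2, atanh ρ, log σ_item, log σ) are sampled with `emcee` using
differential-evolution moves, which mix markedly better than the default
stretch move on these posteriors. Initialization is moment-based (cell
means per participant × half). Halfway through warmup, walkers whose log
posterior lies far below the ensemble maximum (> 25 × dim) are re-seeded
near the best walker: near-degenerate data (residual SD → 0) produce
razor-thin posteriors that can otherwise strand part of the ensemble.

Sampler presets: default 32 walkers × (500 warmup + 1000 kept);
`ModelSpec.reduced()` uses 16 × (300 + 400) and is what the test suite and
the narrative drivers use, trading some effective sample size for wall
time. Convergence is assessed with split-R-hat ≤ 1.01 and ESS ≥ 400 on the
ρ draws (walkers treated as chains — a heuristic for ensemble samplers);
results failing the thresholds are returned with `converged: false` rather
than raised, and a summary whose mean falls outside its own quantile
interval (possible under heavy multimodality from stuck walkers) is widened
and flagged. Per-participant effect estimates are Rao-Blackwellized: the
Gaussian conditional mean E[u | y, θ] is averaged over a thinned set of
hyperparameter draws.

The accuracy model is binomial with a logit link: correct ~ Bernoulli with
logit p = α_c + a_ic, condition intercepts α_c ~ Normal(0, 1.5) (log-odds),
participant effects (a_i1, a_i2) ~ MVN with half-Normal(0, 1) SDs and
LKJ(2) correlation. Because counts per participant × condition are
sufficient, the per-participant 2-D integral over (a_i1, a_i2) is evaluated
by 16² Gauss–Hermite quadrature rotated through the Cholesky factor of the
effect covariance, and the 5 hyperparameters are sampled with the same
ensemble machinery. All-correct participants pose no separation problem —
partial pooling shrinks their effects toward zero.

## Speed–accuracy correlation

Per-participant posterior-mean speed and accuracy effects are correlated
with a Bayesian estimator of a single Pearson correlation: prior on ρ is a
Beta(a, b) stretched from [0, 1] to [−1, 1] (default Beta(3, 3), symmetric
about 0, downweighting |ρ| ≈ 1; Beta(1, 1) gives a flat prior); likelihood
is the exact bivariate-normal sampling density of the observed sample
correlation r given (ρ, n) in its Gaussian-hypergeometric form. The
posterior is computed on a 2001-point grid over (−1, 1) and summarized as a
discrete distribution on that grid (mean, grid-point 2.5/97.5% quantiles,
inverse-CDF draws); the discrete summary stays coherent even when |r| ≈ 1
piles the mass against a support boundary. Because both inputs are point
summaries of posteriors, their own uncertainty is not propagated; this
mirrors the two-stage practice the pipeline implements and is a known
limitation.

## ROPE bands

Correlations are graded into poor (< 0.41), moderate [0.41, 0.61), good
[0.61, 0.81), excellent [0.81, 1]. The conventional two-decimal table
leaves the gaps (0.60, 0.61) etc. unspecified; bands are implemented as
contiguous intervals closed on the left at the printed lower edges, and the
edges are configurable. If the 95% interval sits inside one band the label
is granted "exactly"; otherwise the label of the band containing the lower
bound is granted "at_least" — the measure is only credited with the lowest
reliability its interval still allows.

## Synthetic cohorts

The generator emulates a two-session online naming study: P participants ×
I items per session, identical item sets across participants within a
session, disjoint (counterbalanced two-list) item sets across sessions by
default (`shared_items=True` for same-list designs). A trial's log latency
is μ_c + b_ic + g_j + ε. The joint participant vector (b_1, b_2, a_1, a_2)
(speed and accuracy effects per session) is drawn from a zero-mean Gaussian
whose correlation matrix combines ρ_subj (speed across sessions), ρ_acc
(accuracy across sessions), and the within-session speed–accuracy
correlations, with cross terms completed by the product rule
corr(b_c, a_c′) = ρ_subj ρ_speed-acc; the matrix is checked for positive
semi-definiteness before sampling. Defaults: P = 50, I = 150, μ = 6.75,
τ = 0.15, σ_item = 0.10, σ = 0.30, ρ_subj = 0.77, accuracy grand mean 3.0
log-odds with SD 0.5 (≈ 93% correct overall once disfluencies at 0.6% and
omissions at 1.2% are planted), i.e. the near-ceiling regime of good-faith
naming data. Disfluencies and omissions are planted independently of
latency — no joint mechanism is modeled. Response timing places picture
onset 500 ms into the trial (after a fixation cross) and treats the
3000 ms response window as running from picture onset. Trial-order effects
(practice, fatigue) are deliberately not modeled.

What passing tests do and do not show: recovery tests demonstrate that the
pipeline estimates what the generator planted under the model's own
assumptions (lognormality, homoscedastic residuals, independent error
planting). Real naming data can violate all of these (contaminant slow
tails, order effects, item-by-participant interactions), so recovery here
is a necessary, not sufficient, check for applied use.

The expected naive split-half correlation has the closed form
τ²/(τ² + σ²/m) within a condition (m trials per half; item effects shared
by all participants shift every mean equally and cancel) and
ρ τ_1 τ_2 / √((τ_1² + σ²/m)(τ_2² + σ²/m)) across conditions. For random
even/odd splits the within-condition form is approximate — each participant
averages a different random half of the items — but the item contribution
is O(σ_item²/m) and small at these sizes.

## List balancing

Norms (Zipf frequency, AoA, H-index) are z-scored (sample SD, n − 1;
configurable) into 3-vectors; a perfect matching of the items is sought by
sampling random matchings (shuffle, pair adjacent) and keeping the one with
the highest mean pairwise cosine similarity (default 10⁶ samples); each
pair is then split between the two lists by a fair coin under the run seed.
A caveat found while validating: cosine similarity aligns feature-vector
*direction*, not magnitude, so the resulting lists are not guaranteed
tighter in per-feature means than a random split; the coin-flip assignment
makes the list-mean gap mean-zero with variance (4/n²)·Σ‖within-pair
difference‖² per feature, and that is the property the tests assert. Users
who need strict mean balance should check the per-list summary table the
pipeline emits.

## Power planning

Attenuation uses the classical Spearman correction
ρ_obs = ρ_true √(rel_A rel_B). Power for the two-sided test of ρ = 0 maps
the t-critical value to r_crit = t/√(t² + n − 2) and integrates the exact
density of r under the alternative (adaptive quadrature of the
hypergeometric form, log-space evaluation for large n); `required_n`
brackets and bisects the monotone power curve. The Fisher-z closed form is
exposed as `method="fisher"` and agrees with the exact search within ±2
across the planning range. One boundary case is worth knowing: at
ρ_obs = 0.224 the exact power at n = 153 is 0.79958 — numerically just
below the 0.80 target (confirmed by Monte-Carlo to ±0.0009), so the exact
search returns 154 where tools that display power to fewer digits report
153. No tolerance is applied to the power comparison.

## Problem sizes used by the test suite

Unit tests run on small cohorts (≈ 15 × 20); model-validation and
acceptance tests run at the full design size (50 × 150 × 2) with the
reduced sampler preset, using 10 seeded recovery replicates across true
correlations {0.5, 0.77, 0.9} — sizes chosen to keep a desk-scale run of
the whole suite in minutes. Recovery accuracy is measured against the
realized correlation of the planted participant effects: at 50
participants the realized correlation of the drawn effect pairs differs
from the nominal parameter by ±0.1 routinely, and that gap is sampling
error of the cohort draw, not estimator error.

## Known limitations

- With 150 trials per half and residual SD 0.30, per-half measurement
  reliability is ≈ 0.97, so the naive Pearson-of-means is attenuated by
  only ~3% — comparable to, and sometimes smaller than, the regularizing
  prior's shrinkage of the Bayesian posterior mean at 50 participants. The
  hierarchical model's advantage over averaging grows as trials per half
  shrink or residual noise grows; at these sizes the two estimators are
  close and the hierarchical point estimate is not uniformly more accurate.
- Ensemble-sampler diagnostics (walkers as chains) are optimistic relative
  to independent-chain R-hat; the reduced preset trades ESS for speed and
  can flag `converged: false` on hard posteriors.
- The Bayesian correlation step consumes point estimates of participant
  effects; full uncertainty propagation (joint modeling) is out of scope.
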