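# Methods

## Model structure and assumptions

`trophocc` fits a joint model of two linked observation processes at the
same survey points in burned conifer forest:

1. **Woodpecker occupancy with imperfect detection.**  Within a point-year
   visit, occurrence `z_jt` is assumed closed across the (at most six)
   2–3 minute detection intervals; each conducted interval is a Bernoulli
   trial with probability `z_jt * p_jkt`, where detection depends only on
   survey type (passive listening vs. call broadcast).  Surveys follow a
   removal protocol: intervals after the first detection of a visit are
   not conducted and enter the likelihood as censored (contribution 1).
   Across years, occupancy is an autologistic process — the logit of
   `psi_jt` gains `phi * z_j,t-1` from the second post-fire year onward —
   so persistence is modeled without an explicit year effect.

2. **Beetle-sign intensity.**  Cumulative woodboring-beetle sign at a
   point is treated as a latent continuous intensity in (0, 1), a
   *deterministic* logit-linear function of years since fire, pine
   proportion, and their interaction.  No residual noise is placed on
   intensity; parameter uncertainty propagates through the four gamma
   coefficients.  The only direct beetle observation is the final-year
   summed activity score, Binomial(numTrees × 8, intensity at t = T),
   where 8 is the maximum per-tree score.  Because intensity also enters
   the occupancy regression (main effect and age interaction), the gammas
   are informed by both data streams.

Notable exclusions, by design: no independent effect of time since fire on
occupancy (temporal change must flow through beetle intensity or the
autologistic term), no spatial random effects, one detection covariate
(survey type), two survey types only.

## Time indexing and the first modeled year

Model years t = 1..T are calendar years anchored so the reference year
(2018, the only year with beetle surveys) is t = T; with the earliest fire
burned in 2008, T = 10.  Each point's latent series starts at its *first
post-fire year*, where the no-autologistic (first-year) form of the
occupancy logit applies; pre-fire years are not modeled.  This convention
avoids defining occupancy probabilities for years before a late-burning
fire existed.  Point-years with no surveys contribute an emission of 1 for
both latent states — explicit missingness, not pseudo-zeros.

## Covariates and standardization

* **Snag density index**: the three diameter-class count categories
  (`<=5, 6-15, 16-30, 31-50, 51-100, >100`) map to 1, 6, 16, 31, 51, 101
  and are summed.  For model years without a snag survey the nearest
  surveyed year's index is carried over (ties resolve to the earlier
  year); snag structure changes slowly relative to the survey cadence.
* **Standardization**: elevation, latitude, snag index and years since
  fire are z-scored (sample SD) over the modeled point-years before
  fitting; pine proportion and intensity stay on their natural [0, 1]
  scales.  The constants are stored with the dataset and with every draws
  table, so predictions accept natural units and the transform is
  invertible.  Standardizing fire age matters substantively, not just
  numerically: with the reported coefficient magnitudes, only an age
  variable centered mid-study puts the occupancy-slope crossover
  (−beta_beetle / beta_ageXbeetle ≈ 0.2 on the fitted scale) at ≈ 6 years
  after fire, reproducing the reported positive-early / negative-late
  pattern.  Recovery experiments generate and fit on the same scale, so
  their conclusions are scale-invariant.

## Likelihood: exact marginalization

Rather than sampling the ~128 × 10 binary occurrence states, the
likelihood sums over all 2^T latent sequences per point with a scaled
two-state forward recursion (transition probabilities are the occupancy
probabilities evaluated at z_prev = 0 and 1; emissions are products of
interval Bernoulli terms, computed from per-type detection and
non-detection counts).  This makes the posterior over parameters identical
to the augmented formulation while rendering the likelihood deterministic
— which enables a brute-force enumeration oracle
(`site_marginal_loglik_enumeration`) that the test suite holds to 1e−10
agreement across randomized instances, and lets the sampler reuse cached
components.  Emission terms use `xlogy`/`xlog1py` so zero counts
contribute exactly zero even when a proposed detection probability
saturates, and per-year normalization of the forward variables prevents
underflow over long series.

## Priors

Vague Normal(mean 0, precision 0.1) on every fixed effect, the
autologistic term, and the intercept hyper-mean; fire intercepts
`Normal(mu_beta0, tau_beta0)`.  The hyperprior on `tau_beta0` is
Gamma(shape 0.1, rate 0.1), the conventional vague conjugate choice in
this modeling idiom; it is an explicit constant in `trophocc.likelihood`
for sensitivity runs.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs on the marginalized
posterior, blocked by submodel: (detection intercept + broadcast effect),
(occupancy slopes + phi), per-fire intercepts (proposed jointly, accepted
per fire — fires are conditionally independent given the rest), and the
gamma block, whose Metropolis ratio includes both the binomial beetle
term and the occupancy component that shares the intensity.  `mu_beta0`
and `tau_beta0` are drawn exactly from their conjugate normal and gamma
conditionals.  During burn-in each block adapts a per-coordinate spread
(running moments) and an overall log-scale nudged toward the target
acceptance rate (0.3 for multivariate blocks, 0.44 for the scalar
per-fire updates); adaptation freezes at the end of burn-in, so the
retained kernel satisfies detailed balance.  Runs are deterministic given
(data, config, seed); chains use independent seed-sequence streams.

The default configuration mirrors the original study — 3 chains × 50,000
iterations, thinned by 50 after a 50,000-iteration burn-in, retaining
3,000 pooled draws — with the Gelman–Rubin threshold of 1.1 as the
convergence gate.  All values are configurable, and the shipped
experiments use shorter runs (below).

Two API conveniences support validation: `submodel="beetle"` samples only
the gamma block against the binomial likelihood (for datasets without
detection data), and `fixed=` freezes named coordinates, which the tests
use to compare the one-dimensional detection-intercept posterior against
dense-grid quadrature.

## Synthetic data

The generator runs the model forward under the exact fire-level layout of
the field study (22 fires burned 2008–2017; 4–6 beetle points each, 128
total; staggered survey years with gaps; beetle surveys only in 2018) or
under configurable enlarged designs.  Field covariate distributions are
not recoverable from published summaries, so the defaults are stated
assumptions: fire-level elevation Uniform(1200, 2400) m and latitude
Uniform(35.5, 41.5)° with small within-fire jitter, pine proportion
Beta(2, 2) (Uniform or fixed on request), six snags sampled per point
with occasional shortfalls to 4–5 (reproducing 128 = 22 × 6 − 4), and
snag-count categories drifting downward with fire age as snags fall.
Detection intervals follow the field layout — every point gets the
three-interval broadcast survey, alternating points are preceded by the
three-interval passive survey — with removal censoring applied.  Default
generating truths are the field study's posterior means; the unreported
between-fire intercept precision defaults to `tau_beta0 = 1`.

What the generator does *not* emulate: spatial autocorrelation among
points, observer heterogeneity, year effects beyond the autologistic
term, and misclassification of beetle sign.  Passing recovery tests
therefore demonstrate correctness of the fitting machinery under the
model's own assumptions, not robustness to their violation in real data.

## Problem sizes and numerical choices in the shipped experiments

* Beetle-submodel recovery: 1,000 points (ages uniform on 1..10 via ten
  equal pseudo-fires, pine Uniform(0,1), 48 trials per point), 3 chains ×
  4,000 iterations after 2,000 burn-in, thin 4.  Posterior means match an
  independent maximum-likelihood binomial GLM fit to the same data to the
  third decimal.
* Joint-model recovery: 100 fires × 6 points × 10 years with every
  post-fire year surveyed, 3 chains × 10,000 iterations after 4,000
  burn-in, thin 10 (about 90 s on one CPU).
* Interval calibration: 20 replicates of a 250-point beetle experiment;
  coverage of the four 95% intervals is tested against nominal with a
  binomial test at alpha = 0.01.
* Tolerances: forward-vs-enumeration 1e−10; standardization uses sample
  (ddof = 1) SDs; equal-tailed quantile intervals (not HPD), matching the
  summaries the model class is conventionally reported with.

## Known limitations

* The original field data are not distributed, so agreement with the
  published fit is assessed by simulation-based recovery at the published
  posterior means, not by refitting the real data.
* The between-fire intercept precision used as a generating truth is an
  assumption (the study reports no value).
* Identifiability of `beta_beetle` separately from `beta_ageXbeetle` is
  weak (intensity is itself a smooth function of age); its posterior is
  wide in both the original study and the recovery experiments, and the
  sampler's blocking reflects that correlation structure rather than
  resolving it.
* With `phi` and fire intercepts both absorbing temporal persistence,
  short series (fires burned late in the study) contribute little
  information about `phi`; recovery of `phi` is correspondingly slower
  than of the regression slopes.
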