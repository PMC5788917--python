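# Methods

## The model

Each trial is one rater re-rating one image after seeing genuine peer
information. Raw ratings `X` on the hidden 0–100 slider are mapped onto the
open unit interval by

    Y = (X/100) * 0.999 + 0.0005

so that 0 and 100 land at 0.0005 and 0.9995, strictly inside the support of a
beta distribution. The final rating is modelled as

    final_u ~ Beta(mu * phi, (1 - mu) * phi)
    mu      = logistic( logit(I) + s_{p,c} * (logit(S) - logit(I)) )
    s_{p,c} = beta_c + u_p,      u_p ~ Normal(0, sigma_u^2)

where `I` and `S` are the initial and displayed peer rating on the unit
scale, `beta_c` is the social-influence slope for stimulus condition `c`
(faces, hands, abstract art) and `u_p` is a participant random slope. The
slope has a direct behavioural reading: `s = 0` reproduces the initial
rating, `s = 1` adopts the peer rating, values in between interpolate,
`s > 1` over-adjusts and `s < 0` is contrarian. Both endpoint identities
hold exactly under the default logit-scale interpolation and under the
raw-scale variant (`ModelSpec.link_scale = "raw_interpolation"`, mean
clamped to [1e-6, 1 - 1e-6]), for any real slope.

Where the slope enters the link is a genuine modelling choice: a beta GLMM
with a logit link admits either interpolation on the log-odds scale or on
the raw scale. The default interpolates on the log-odds scale because it
preserves the 0/1 endpoint semantics while keeping the mean interior for
*any* real slope without clamping; the raw-scale variant is retained for
sensitivity analysis.

Priors: `beta_c ~ N(0, 1)`; `sigma_u^2 ~ Exp(1)`; `phi ~ Exp(1)`. The
beta likelihood is parameterised by mean and precision (`alpha = mu*phi`,
`beta = (1-mu)*phi`) with a single precision shared across trials; the
exponential hyperprior is read as a prior on that precision. The random
participant effect's normal law is the conditional (hierarchical) prior
`N(0, sigma_u^2)`, not an independent fixed-variance prior. Robustness
variants: `flat_prior_variant=True` widens the condition-slope priors to
variance 100 (slopes only), and `random_effect_structure="per_condition"`
gives each participant one slope per condition. A third structure,
`"none"`, removes the random effects entirely; it exists so that tiny toy
posteriors can be checked against brute-force quadrature.

## Posterior computation

The sampler is adaptive random-walk Metropolis-within-Gibbs over
`(beta_c, u_p, log sigma_u^2, log phi)`. Because trials partition by
condition given `u` and by participant given `beta`, the full conditionals
of the `beta_c` (and of the `u_p`) factorise, so each block is proposed and
accepted component-wise in one vectorised step. Log-transformed variance
and precision moves include the Jacobian. One extra move handles the weak
identifiability of the common level (`s` depends on `beta` and `u` only via
sums): a translation that adds `d` to every condition slope and subtracts
`d` from every participant slope leaves the likelihood invariant and is
accepted on the prior ratio alone. Without it the condition slopes mix an
order of magnitude more slowly.

Per-parameter step sizes adapt toward a 0.44 acceptance rate every 25
sweeps during burn-in only, so kept draws come from a fixed kernel and
detailed balance holds. Chains are initialised overdispersed (slopes from
their prior, `u = 0`, variance and precision at 1, log-perturbed) from
per-chain substreams of a single seed; identical configuration reproduces
draws bit-for-bit. The contract is the posterior, not the algorithm: the
sampler is validated against a 200x200 grid quadrature of a 3-trial toy
posterior (agreement within 0.02 in posterior means) and by parameter
recovery at the study's scale.

The replication budget is 3 chains x 50,000 iterations, burn-in 5,000,
thinning every 10 (4,500 kept draws per chain). Tests and recovery studies
use a desk-scale budget of 3 x 5,000, burn-in 1,000, thinning 5 (800 kept
per chain), which yields effective sample sizes around 1,500–1,800 for the
structural parameters at the study's scale — ample for medians and 95%
intervals.

## Diagnostics and summaries

* PSRF is the original Gelman–Rubin statistic, `sqrt(V/W)` with
  `V = ((n-1)/n) W + B/n`, not the split-chain variant, with the F-based
  97.5% upper limit; two bit-identical chains give the degenerate
  `sqrt((n-1)/n) < 1`.
* ESS uses Geyer's initial-positive-sequence truncation of the
  autocorrelation sum (FFT autocovariance, consecutive pairs added while
  positive), computed per chain and summed. A constant chain reports ESS =
  n with a warning. Definitions of ESS vary across tools; this one is
  documented precisely because interval-based comparisons depend on it.
* Summaries pool draws across chains and report the median and equal-tailed
  credible interval using linear (type-7) quantile interpolation; interval
  endpoints at two decimals can shift under other quantile types.
* Condition contrasts are computed draw-wise (same chain, same iteration)
  and then summarised identically.
* The fit check reports the Pearson correlation between per-trial
  posterior-mean predictions and observed final ratings *and* its square:
  the two are distinct quantities even though "pseudo-R^2" is sometimes
  used for either. Predictions are conditional (each trial uses its own
  participant's slope draws), i.e. a within-sample fit measure.

## The simulator

The generator reproduces the experiment's structure: groups of 5–10 raters
(defaults: 6 groups), every member rating the same within-group image set
of 10 faces + 10 hands + 10 artworks (30 trials each), split into three
blocks of 10 or six blocks of 5; the displayed peer rating is the mean of
all other members' initial ratings, of the highest two, or of the lowest
two, drawn independently per trial with probability 1/3 each.

Initial ratings are simulated on the log-odds scale as a shared image
quality effect `N(0, 0.7^2)` plus independent rater noise `N(0, 1)`,
mapped through the logistic and back to the raw slider scale. The shared
image effect induces realistic between-rater agreement, which is what makes
the top-two/bottom-two rules genuinely widen the spread of social
information. The real study does not report its initial-rating
distribution; this law is a modelling choice.

Final ratings are drawn from the fitted model's own generative form with
known parameters, inverse-transformed, and clamped to [0, 100] (only draws
the beta law placed beyond the squeezed image of the slider are affected).
Default generative parameters sit at the study's estimated operating point:
slopes 0.13 / 0.13 / 0.14, random-slope variance 0.06. The beta precision
is not reported by the study; the default `phi = 22` was calibrated once so
that the fitted model's in-sample predicted-vs-observed correlation at the
study's scale matches the reported ~0.92 (pseudo-R^2 ~0.84), which
corresponds to roughly 10 rating points of within-trial noise. Simulated
participants default to orientation score 0, so the simulated sample is the
analysis sample; the heterosexual filter (`orientation_score <= 1` by
default, threshold configurable up to the all-participants variant) is
exercised against explicitly constructed metadata.

What the simulator does *not* emulate: response times, block-order memory
effects, participant dropout, integer-valued slider output (ratings are
real-valued; the study does not state that the slider emitted integers),
and any dependence of rating behaviour on time or trial order. Passing
recovery tests therefore show that the estimator recovers the parameters of
its own generative law at the study's size and noise level — not that the
behavioural model is true of human raters.

## Numerical choices

* Trials where the displayed peer rating equals the initial rating are
  retained: the slope drops out of their likelihood, but they still inform
  the precision. With *only* such trials the slope posteriors fall back to
  their priors (checked by a Kolmogorov–Smirnov test against N(0, 1)).
* The likelihood clips the beta mean to [1e-12, 1 - 1e-12]; invalid states
  (non-positive variance or precision) get log prior -inf and are rejected
  rather than raising.
* Quantile method, PSRF variant and ESS truncation are as above; ties in
  `top2`/`bottom2` peer selection are resolved by value (any two maximal
  values give the same mean).
* Recovery studies exclude (and list) replicates with PSRF >= 1.1 on any
  structural parameter; at the study's scale with the desk budget none are
  excluded in practice.

## Problem sizes used by the test suite

Parameter recovery runs 20 replicates of 42 raters x 30 trials (6 groups of
7) at the desk-scale MCMC budget; the quadrature comparison uses a 3-trial
toy with 3 x 20,000 iterations; diagnostics checks use 3 x 5,000–10,000
i.i.d. or AR(1) draws; the simulator's rule-frequency check uses ~10,000
trials. These sizes were chosen so the full suite runs in minutes on a
laptop while keeping Monte-Carlo error well inside every asserted
tolerance.

## Known limitations

* The likelihood ignores the boundary mass created by clamping simulated
  ratings to the slider range, which biases the recovered precision
  slightly low (about -0.6 of phi = 22 at the study's scale); slopes and
  the random-slope variance are unaffected within Monte-Carlo error.
* A single precision is shared across conditions and participants.
* The sampler is random-walk based; for much larger designs a
  gradient-based sampler would scale better (out of scope here).
* Group-level effects (images are nested in groups) are not modelled,
  mirroring the analysed design where each image set is group-specific.
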