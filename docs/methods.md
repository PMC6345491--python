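# Methods

## Model

Each site-unit — one point-count location in one winter — has a latent
occupancy state `z_i ~ Bernoulli(ψ_i)` and, conditional on occupancy,
independent detections `y_ij ~ Bernoulli(p_ij)` on its J=2 replicate
visits. Both probabilities are logistic-linear: `logit ψ_i = x_i'α`,
`logit p_ij = w_ij'β`. Assumptions inherited from the design: closure
(the occupancy state does not change between a winter's two visits),
independence of site-units (points within the same wetland share the
wetland's type and size covariates but no random effect — none appears in
the model being emulated), and no false positives. Year enters occupancy
as a two-level categorical covariate, so the two winters at a point are
separate site-units.

Missing visits are dropped from the detection likelihood (rows are simply
absent from the detection design matrix `W`), not imputed. Likelihood
evaluation always uses the z-marginalized site likelihood computed in log
space with `logaddexp`, so extreme coefficients cannot underflow; the
latent `z` appears only inside the sampler.

## Covariate encoding

Continuous covariates (wetland size, time, wind, temperature, noise, day
of season) are z-standardized with the sample mean/SD of the rows entering
the fit; categorical covariates are dummy-coded against the first level of
their declared level order (e.g. type=ACEP, shrub cover 0–50%). The
`encoding_record` stores every mean/SD/median and reference level, so raw-
scale coefficients, profiles and odds-ratio reference points are always
recoverable, and a frozen record can be re-applied to new data.
Standardization is computed at the site-unit (point-year) level — the
pooled alternative (one mean per point across years) differs only through
year-to-year covariate changes and is not implemented.

A pre-fit collinearity screen reports all pairwise absolute correlations
among occupancy covariates (categorical ones via integer level codes) and
flags pairs at |r| ≥ 0.5; constant columns yield an undefined (NaN,
unflagged) correlation rather than an error.

## Priors and sampling

All coefficients have standard logistic(0, 1) priors — the prior under
which an intercept pushed through the inverse logit is exactly
Uniform(0, 1). The sampler is data-augmented Metropolis-within-Gibbs:

1. Gibbs draw of each `z_i` from its Bernoulli full conditional
   (`z_i = 1` with certainty wherever the species was detected);
2. componentwise Gaussian random-walk Metropolis updates of α against the
   complete-data occupancy likelihood and of β against the detection
   likelihood restricted to currently-occupied site-units, each plus the
   prior.

Proposal standard deviations start at 1 and adapt every 50 iterations
during burn-in by `scale *= exp(0.5·(rate − 0.3))`, targeting ~30%
acceptance; adaptation freezes at the end of burn-in so retained chains
are Markov. Chains initialize at α = β = 0 apart from an N(0,1)-dispersed
intercept, with `z` set to 1 where any detection occurred and Bernoulli(0.5)
elsewhere. The original analysis used a general-purpose Gibbs engine whose
internals are unspecified; any correct sampler targeting the same
posterior is equivalent in distribution, which is what the validation
tests assert (prior-only sampling recovers the logistic marginal by KS
test; simulated-data fits cover the generating values).

Defaults mirror the reference protocol: 4 chains × 10,000 iterations,
thin 5, burn-in 5,000 for song and swamp sparrow and 2,500 for dark-eyed
junco and white-throated sparrow (config-overridable). The bundled
analysis scripts and the acceptance script run a quarter-scale version
(2,500 iterations, burn-in 1,250/625) — chosen as sufficient for stable
summaries at the simulated data size (max split R-hat ≈ 1.01–1.09 in the
worked example), with the same chain count and thinning.

Diagnostics: classic split-chain Gelman–Rubin R-hat (each chain halved; no
rank normalization, matching the era of tooling being emulated); NaN where
within-chain variance is zero. Posterior intervals are equal-tailed
empirical quantiles with linear interpolation of order statistics
(Hyndman–Fan type 7), stated so interval tests are exact.

## Model selection

WAIC with the variance penalty (pWAIC2): `lppd = Σ_i log mean_s exp(ℓ_is)`
via a stable log-mean-exp, `p_waic = Σ_i var_s(ℓ_is)` with the S−1
denominator, `WAIC = −2(lppd − p_waic)`, where `ℓ_is` is the integrated
site log-likelihood (the latent state makes per-visit terms
non-exchangeable, so the site-unit is the pointwise unit). The penalty
variant is unstated in the protocol being emulated; the variance form is
the standard recommendation and is fixed here so tests are exact.

Reduction rule: a covariate is retained iff at least one of its
coefficients has a 50% credible interval excluding 0; categorical
covariates are kept or dropped as whole dummy blocks; intercepts always
stay; the rule applies independently to the occupancy and detection lists
and is idempotent given the same fit. Comparison tables report
K = number of coefficient columns (intercepts included) and ΔWAIC from the
best model, ties broken toward fewer parameters.

A statistical consequence worth stating: under a symmetric posterior
centered near zero, a truly-null coefficient's 50% interval excludes zero
with probability ≈ 0.5, so reduced models are expected to retain roughly
half of the null covariates. The full-loop test therefore asserts strong
true effects (|1.5| log-odds) are retained in ≥ 80% of replicates while
null covariates are dropped at a rate consistent with the rule (observed
well above 30%), not that nulls are (almost) always dropped — no
reduction rule of this form can deliver that.

## Richness model

Apparent richness (distinct species per wetland-year, uncorrected for
detection) is Poisson with log mean linear in wetland type, standardized
size, and year. The fit is IRLS (Fisher scoring) run to a relative
deviance change below 1e-10 (max 100 iterations), with a rank check that
rejects duplicated or collinear columns, and Wald z / normal-approximation
p-values. No overdispersion correction is applied — the emulated analysis
reports a plain Poisson fit — so standard errors are anti-conservative if
richness is overdispersed. Wetland-year is the replication unit (year is a
model term, which requires per-year counts).

## Synthetic-data generator

The generator reproduces the *design envelope* of a two-winter survey of
33 wetlands (20 ACEP, 13 reference): per-wetland size log-uniform on
0.28–32.4 ha; points per wetland `1 + Binomial(8, 3/8)` (support 1–9,
mean 4); two years × two visits; continuous survey covariates uniform over
their observed ranges (e.g. wind 0–4.5 m/s, noise 0–67 dB, day of season
1–102); categorical covariates multinomial with the observed level
proportions (e.g. shrub cover at 1×1 m: 0.77/0.23). Detections are drawn
from exactly the logistic-linear model the estimator assumes; richness
from the Poisson log-linear model. Default species effects are centred on
the reported field estimates (song sparrow: shrub −2.6, day-of-season
−1.1; junco: size −1.6, time +0.8; swamp sparrow: size +2.4, wind −0.9;
white-throated sparrow: water +3.2), so the synthetic study reproduces the
qualitative structure of the real one, including the opposite size effects
of junco and swamp sparrow.

What the generator does **not** emulate: empirical joint distributions and
spatial structure of covariates (everything is drawn independently within
a wetland), between-point dependence beyond shared wetland covariates,
observer effects, and model misspecification of any kind. Passing tests
therefore demonstrate correctness of the inference machinery under the
assumed model and realistic sample sizes — not robustness of the model to
real field data. The latent occupancy table is written with a
`_synthetic` suffix for white-box testing and is never read by any
fitting path.

## Numerical choices and degenerate inputs

- Likelihood, priors and the z-conditional all operate on the logit scale
  with `logaddexp`; `inv_logit(±800)` is exact 1/0 without warnings.
- Zero-variance continuous covariates are a validation error at encoding;
  unknown categorical levels likewise.
- WAIC requires ≥ 2 draws (variance undefined at 1); R-hat requires ≥ 2
  chains and ≥ 4 retained draws per chain.
- Retained-draw bookkeeping is exactly
  `n_chains · floor((iterations − burnin)/thin)` and is asserted at run
  time.
- MCMC reproducibility: one `SeedSequence` per run, spawned per chain;
  identical configs give bit-identical draws.

## Limitations

- No wetland-level random effect: points in the same wetland are
  conditionally independent given covariates, as in the emulated analysis;
  occupancy SEs may be optimistic if within-wetland correlation exists.
- Componentwise random-walk sampling mixes slowly for strongly correlated
  coefficients (e.g. near-separated categorical levels); R-hat is reported
  and flagged above 1.1 precisely because of this.
- The richness model ignores detection; "apparent" richness comparisons
  are biased low in a way that can differ between wetland types if
  detectability does.
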