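# Methods

## The scientific problem

Traffic disturbance depresses wildlife activity in a band of habitat along
major roads — the *road-effect zone*. For insectivorous bats the zone is
measured acoustically: detectors placed at increasing distances from a
freeway record echolocation call sequences ("calls"), and the change in
nightly call counts with distance estimates how far the depression extends.
This package implements that analysis as a reusable, testable pipeline:
survey simulation, call filtering, hierarchical Bayesian inference, and
zone computation.

## The activity model

For detector-night `i` with call count `R_i`:

    R_i ~ Poisson(lambda_i)
    ln(lambda_i) = beta0 + beta1*D_i + beta2*T_i + beta3*L_i + beta4*C_i
                   + eps_x(i)

* `D_i = log10(distance_m + 1)` — distance from the freeway enters on a
  log scale (road effects attenuate with distance; +1 keeps 0 m finite).
  **The Poisson link is the natural log while the distance transform is
  base 10.** This mixed convention is deliberate: it is the only
  combination under which the published combined coefficient
  (beta1 = 0.274) reproduces the published zone distances (20% decline at
  ≈307 m; a natural-log distance transform would put it at ≈885 m). The
  pre-build check in `tests/test_acceptance.py` enforces the
  reconciliation.
* `T_i`, `C_i` — daily minimum temperature (°C) and canopy cover (%)
  centered on their mean and scaled to unit SD ("standardized"). A
  center-only mode is available (`standardize_mode="center"`) because the
  field convention is ambiguous; z-score is the default, and fitted-mean
  predictions are invariant to the choice after back-transformation
  (tested).
* `L_i` — count of large trees (diameter > 30 cm at breast height within
  10 m of the detector), entering raw.
* `eps_x ~ Normal(0, sigma^2)` — exchangeable per-transect random effect;
  no spatial correlation between transects is modelled.
* Priors: Uniform(−10, 10) on every coefficient; Uniform(0, 10) on sigma.
  The sigma prior mirrors the vague-uniform style of the coefficient
  priors; it is a package choice, as is fitting on the SD scale.

An alternative distance form (`linear_standardized`: z-scored raw metres)
exists solely for DIC model comparison; on data generated under the log10
form the log10 model attains lower (or within-2-units) DIC, and the suite
checks that direction on simulated replicates.

## MCMC sampler

Adaptive Metropolis-within-Gibbs: each coefficient, each transect effect
and sigma get componentwise Gaussian random-walk proposals. Proposal
scales adapt by Robbins–Monro (`log s += (acc − 0.44)/sqrt(batch)` every
50 iterations) **during burn-in only**, so retained draws target the exact
posterior. Two reparameterisations address the posterior correlations
this model creates:

1. Non-intercept design columns are centered internally; the intercept is
   mapped back to the uncentered scale (baseline at 0 m, mean covariates,
   no large trees) on every stored draw and for prior-bound checks.
2. A likelihood-invariant translation move proposes `beta0 + d,
   eps − d` jointly, breaking the intercept/random-effect ridge.

Initialization is by penalised IRLS on the fixed effects (transect effects
at 0, sigma at 0.5), with up to 10 jittered retries if a finite posterior
cannot be found. Chains are seeded from a single `SeedSequence`, making
fits bitwise reproducible. Correctness is enforced by an analytic oracle:
on an intercept-only model the MCMC rate posterior must match the
conjugate Gamma(Σy, n) posterior with Kolmogorov–Smirnov distance < 0.02
at 30,000 kept draws. On study-sized synthetic data, desk-scale chains
reach R-hat < 1.01 for every reported parameter (tested).

Default ("desk-scale") protocol: 3 chains × 12,000 iterations, 2,000
burn-in, thinning 2 (5,000 kept per chain).
A publication-scale preset (3 × 400,000, 100,000 burn-in, thin 10) is
available via `MCMC_FULL` / `--full-mcmc`. Model-comparison and
property-test replicates inside the suite use shortened protocols
(6,000/1,500/2 and 4,000/1,000/2), which suffice for DIC ordering and
interval coverage.

Diagnostics: classic Gelman–Rubin R-hat, `sqrt(((n−1)/n·W + B/n)/W)` with
`W` the mean within-chain variance and `B` the scaled between-chain
variance of chain means; DIC conditional on the transect effects
(`p_D = mean deviance − deviance at the posterior mean`), matching what a
generic Gibbs engine reports for this model. A single-transect dataset
cannot identify sigma; the model warns and fits with the random effect
disabled.

## Road-effect zone

With beta1 > 0, predicted activity at mean covariates,
`exp(beta0 + beta1·log10(d+1))`, increases monotonically, so its maximum
over the sampled range [0, d_max] sits at d_max (2,000 m by default, the
farthest detector). The zone at decline threshold `p` solves
`activity(d) = (1−p)·activity(d_max)`:

    d = (d_max + 1)·(1 − p)^(ln 10 / beta1) − 1

rounded to the nearest metre (half away from zero), with the inverse
`beta1 = ln 10 · ln(1−p) / ln((d+1)/(d_max+1))` used for cross-checking
printed tables. The maximum is taken from the model-predicted curve, not
per-transect raw maxima — the only reading consistent with the published
multi-threshold table, whose every row inverts to a single coefficient
within 2% relative spread (tested against the packaged transcription).
"No zone" is reported when beta1 ≤ 0 or the *unrounded* boundary falls
below 1 m; the sub-metre rule (rather than sub-half-metre) is what
reproduces the published "-" pattern, including the one species with a
zone only at the 10% threshold, and is a documented choice, not a
published rule. A brute-force 0.1 m grid search (`zone_numeric`) serves as
an independent oracle and agrees with the closed form within 1 m across a
50-point sweep. Zones are computed from posterior-mean coefficients;
computing one zone per posterior draw yields a credible interval on the
zone if wanted.

## Call identification

A call is only identified when it has ≥ 5 pulses and a strict majority
(> 50%) of pulses agree on one species; ties are impossible under the
strict rule. Pulse labels are pooled through the species-complex map
*before* the vote (the two Nyctophilus species and Myotis macropus are
acoustically inseparable, so their pulse assignments legitimately scatter
across the complex); with clean inputs the vote order is immaterial.
Every pulse row is treated as valid — upstream call-quality screening is
out of scope. The manual visual confirmation applied to Austronomus
australis files in the field is represented as a per-call boolean carried
through unchanged. Unknown calls are excluded from the modelled counts and
reported separately; whether they should contribute to the combined
response is an open question in the source analysis, and exclusion is this
package's documented assumption.

## Synthetic data: what it does and does not emulate

The generator reproduces the study's *statistical* structure: the
18-transect × 10-distance × 2-night frame with the realized 280-of-360
pattern (drawn uniformly without replacement per distance), Poisson counts
under the model above, and symbolic pulse tables whose identification
round-trips exactly at zero misassignment. Generator defaults are the
study conditions where stated; where the study is silent they are fixed
plausible choices, not calibrated estimates:

| parameter | default | rationale |
|---|---|---|
| beta1..beta4 | 0.274, −0.176, −0.001, 0.048 | published combined estimates |
| beta0 | 4.0 | not published; gives ≈1.1k identified calls per transect-night, the reported magnitude |
| sigma_transect | 0.5 | not published; moderate between-transect heterogeneity |
| min temp | Uniform(5, 25) °C per transect-night | austral-summer overnight range |
| large trees | Poisson(3) per site | woodland verge density |
| canopy | 10 × Binomial(10, 0.4) % | visual estimates to the nearest 10% |
| pulses per call | 5 + Poisson(4) | typical pass lengths; all identifiable by default |

The generator standardizes temperature and canopy with the realized
sample's own mean/SD — exactly what the fitter does — so generating and
fitted coefficients live on the same scale. Not emulated: acoustic
waveforms (pulses are symbolic labels), spatial autocorrelation between
transects, night-to-night temporal correlation, overdispersion or
zero-inflation, and detectability differences between species. Passing
recovery tests therefore show the estimator is correct *under the model's
own assumptions*; they cannot show robustness to violations real
recordings may contain.

## Numerical choices and degenerate inputs

* Out-of-bound proposals are rejected via −∞ log posterior; overflowing
  Poisson means reject naturally (the simulator, by contrast, raises when
  a linear predictor exceeds a cap, default 30, naming the cell).
* Zero-variance standardized covariates raise rather than silently divide
  by zero; constant tree counts are fine (raw scale).
* R-hat of a pinned (zero-variance) parameter is reported as 1.
* Kept draws per chain are exactly `(iterations − burn_in) // thinning`.
* Posterior intervals are equal-tailed 2.5%/97.5% quantiles; an effect is
  flagged "indistinguishable from zero" when the interval covers 0.

## Problem sizes

The suite's stochastic checks use 20 recovery replicates and 10 DIC
replicates at the 280-cell study size with the desk-scale or shortened
protocols above; the sampler-correctness check uses 30,000 kept draws on a
50-observation dataset. These sizes give Monte-Carlo error comfortably
below the tolerances they are tested at.

## Known limitations

* Single-species coefficient sets are simulated independently; real
  assemblages share nights and weather, inducing cross-species dependence
  the pipeline neither generates nor models.
* DIC is conditional on the random effects; marginal-likelihood-based
  comparison would penalise the hierarchy differently.
* The nominal 10 m stand-in for the 0–10 m detector interval is
  configurable per record but defaults to a fixed value.
* Frequentist coverage of the credible intervals is checked at one
  generative setting; heavy-tailed or sparse-count regimes are untested.
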