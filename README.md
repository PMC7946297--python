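# roadzone

Road-effect zones for insectivorous bats from acoustic transect surveys.

Major roads depress wildlife activity well beyond the pavement edge. For
bats, this *road-effect zone* is measured acoustically: detectors along
transects running perpendicular to a freeway count echolocation calls per
night, and the recovery of call activity with distance locates the zone
boundary. `roadzone` packages that analysis end to end for ecologists and
road-planning practitioners: a survey simulator with the field design's
statistical structure, the pulse-majority call-identification filters, a
hierarchical Bayesian Poisson activity model fitted by MCMC, and the
closed-form zone computation with multi-threshold tables.

## The model

Nightly call counts `R_i` per detector follow

    R_i ~ Poisson(lambda_i)
    ln(lambda_i) = beta0 + beta1*log10(d_i + 1) + beta2*T_i + beta3*L_i
                   + beta4*C_i + eps_x(i)

with `d_i` the distance from the freeway (m), `T_i`/`C_i` standardized
minimum temperature and canopy cover, `L_i` the large-tree count at the
detector, and `eps_x ~ N(0, sigma^2)` a per-transect random effect.
Priors are Uniform(−10, 10) on coefficients; inference is adaptive
Metropolis-within-Gibbs with Gelman–Rubin R-hat diagnostics and DIC model
comparison. For beta1 > 0 the road-effect zone at decline threshold `p`
(the distance within which activity is at least `p` below its maximum
over the sampled range, maximum at `d_max` = 2,000 m) has the closed form

    d = (d_max + 1) * (1 - p)^(ln 10 / beta1) - 1.

See `docs/methods.md` for assumptions, sampler details and limitations.

## Worked example

Simulate the default survey (18 transects × 10 distances × 2 nights,
280 detector-nights realized) with the published all-species coefficient
vector, refit it, and turn the fitted distance coefficient into a zone
table:

```python
import roadzone as rz

design = rz.study_design(seed=0)              # 18 x 10 x 2 frame, 280 realized
covariates = rz.sample_covariates(design, seed=1)
records = rz.simulate_counts(design, covariates,
                             rz.STUDY_COMBINED_COEFS, seed=2)

model = rz.HierarchicalPoissonRegression(random_state=3).fit(records)
print(model.summarize().round(3).head(6).to_string())
print(f"converged: {model.converged_}   DIC: {model.dic_:.1f}")

beta1 = model.coef_["beta_distance"]
table = rz.zone_table({"all species combined": beta1})
print(rz.render_zone_table(table))
```

prints

```
                 mean     sd   q2.5  q97.5   rhat  overlaps_zero
parameter
beta0           3.993  0.121  3.753  4.232  1.000          False
beta_distance   0.276  0.008  0.260  0.291  1.000          False
beta_temp      -0.176  0.007 -0.190 -0.161  1.001          False
beta_trees     -0.000  0.003 -0.006  0.006  1.000           True
beta_canopy     0.042  0.006  0.030  0.054  1.000          False
sigma_transect  0.494  0.093  0.349  0.712  1.000          False
converged: True   DIC: 2133.2
             species 50% 30% 25% 20% 15% 10%
all species combined   5 101 180 309 514 829
```

The generating values (0.274, −0.176, −0.001, 0.048, sigma 0.5) all sit
inside their 95% credible intervals; the tree effect is correctly flagged
as indistinguishable from zero; and the fitted coefficient places the 20%
road-effect zone at ≈309 m — activity within roughly 300 m of the freeway
is depressed by a fifth or more, an order of magnitude wider than a
typical vegetated verge.

The same pipeline runs from the shell:

```
roadzone simulate --seed 1 --out run/
roadzone identify --run run/
roadzone fit --data run/identified_nights.csv --out run/
roadzone zones --fits run/ --out run/
roadzone report --run run/
```

Every output carries the seed and config hash that produced it; repeat
runs with the same seed are byte-identical.

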