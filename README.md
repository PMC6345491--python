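# wetlandbirds

Bayesian single-season occupancy models with imperfect detection, WAIC
model selection, and Poisson richness regression for winter point-count
surveys of wetland birds — with a synthetic-study generator so the whole
pipeline can be exercised and validated without field data.

## The problem

Detection/non-detection surveys underestimate how many sites a species
uses, because a bird present at a site is not always seen or heard. The
single-season occupancy model separates the two processes with a latent
occupancy state per *site-unit* (here: a point-count location in one
winter, visited twice):

```
z_i   ~ Bernoulli(ψ_i),        logit(ψ_i)  = x_i' α      (occupancy)
y_ij  ~ Bernoulli(z_i · p_ij), logit(p_ij) = w_ij' β     (detection)
```

Occupancy covariates `x_i` are wetland type (conservation-easement "ACEP"
vs reference), wetland size, survey year and vegetation cover classes;
detection covariates `w_ij` are per-visit conditions (time of day, sky,
wind, temperature, noise, day of season). Marginalizing `z_i` gives each
site-unit's integrated likelihood

```
L_i = ψ_i ∏_j p_ij^y_ij (1−p_ij)^(1−y_ij) + (1−ψ_i) · 1[Σ_j y_ij = 0]
```

which is the pointwise unit for WAIC. All coefficients carry logistic(0,1)
priors; the posterior is sampled by data-augmented Metropolis-within-Gibbs
(4 chains, split-chain Gelman–Rubin diagnostics). Model selection follows
a two-stage protocol: fit the **global** model with every covariate, then
a **reduced** model dropping each covariate whose coefficients all have
50% credible intervals overlapping 0, and rank the two by WAIC.

Apparent species richness (distinct species per wetland-year, uncorrected
for detection) is modeled separately as a Poisson GLM,
`log E[richness] = γ0 + γ_type + γ_size·size_z + γ_year`, fit by IRLS.

## Worked example

```sh
python analysis/01_simulate_study.py 1     # writes results/data/*.csv
python analysis/02_fit_occupancy.py 1      # per-species fits + selection
python analysis/03_richness_glm.py         # richness GLM
```

The simulation (seed 1) creates 33 wetlands / 238 site-units and prints,
per species, the naive occupancy (share of site-units with ≥1 detection)
next to the true simulated occupied fraction — e.g. song sparrow `naive
0.689 (true occupied fraction 0.828)`, the gap being exactly the imperfect
detection the model corrects for. The fitting step then reports, for the
dark-eyed junco (simulated with a true size effect of −1.6 log-odds per
SD of wetland size):

```
deju: best = reduced, dWAIC = 9.88, max R-hat = 1.038
  reduced occupancy: ['herb', 'shrub5', 'water', 'size', 'year']
  reduced detection: ['time', 'sky', 'temp', 'dist', 'day']
  occupancy at mean covariates (mean site): 0.26 [0.17, 0.36]
```

i.e. the reduced model beats the global model by ~10 WAIC units, the true
size effect is retained by the credible-interval rule, and occupancy at
the average site is 0.26 (95% CI 0.17–0.36) against a true occupied
fraction of 0.31. The richness step prints the coefficient table; with
generating coefficients (type −0.05, size 0.2, year −0.08) it finds only
size clearly associated with richness
(`log proportional change per SD = 0.14, p = 1.6e-06`).

Per-species outputs land in `results/occupancy/<species>/`: posterior
summaries with 50%/95% intervals, the WAIC comparison table, occupancy at
mean covariates by wetland type, and the wetland-size log-odds-ratio curve
(`size_odds_ratio_curve.csv`, relative to the median wetland size).

The same pipeline is available as a library call
(`wetlandbirds.run_pipeline(config)`) or CLI (`wetlandbirds all --config
cfg.yaml`), driven by a YAML config naming either a simulation scenario or
the four input CSVs (detection histories, site covariates, survey
covariates, richness).

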