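# matogive

Maturity-ogive estimation for migratory, spatially structured fish stocks.

A maturity ogive — the proportion of females mature as a function of fork
length — underpins spawning-stock-biomass and reproductive-potential
calculations in stock assessment. For a migratory stock the naive estimate is
biased: if mature fish move to a spawning ground and sampling effort follows
them, fish sampled there are mature at smaller lengths than the population at
large, and a single curve pooled over space and season under-estimates the
length at 50% maturity (L50). `matogive` implements the full analysis chain
that diagnoses and corrects this bias:

1. **Histological maturity classification** — a deterministic rule engine
   maps ovary features (most advanced group of oocytes, postovulatory
   follicles, alpha/beta atresia, maturity markers such as brown bodies and
   residual hydrated oocytes) to development classes C1–C7 and a
   mature/immature, active/inactive call. Maturity markers let regenerating
   (mature but resting) females be told apart from immature ones, so sampling
   can run year-round. Fish under 70 cm are classed immature macroscopically.
2. **Spline logistic mixed models** — maturity (1 = mature) is modelled on
   the logit scale as a function of a natural cubic spline in length (or
   age), latitude and longitude terms, a season factor and their
   interactions, with a Gaussian random intercept per fishing set:

   `logit P(mature) = s(length) + f(latitude) + g(longitude) + season +
   latitude×season + b_set`,  `b_set ~ N(0, σ²)`.

   Estimation maximises the Laplace-approximate marginal likelihood; an
   adaptive Gauss–Hermite quadrature evaluator cross-checks it.
3. **AICc multi-model inference** — candidate models are ranked by
   `AICc = −2 log L + 2k + 2k(k+1)/(n−k−1)` and compared through Akaike
   weights `w_i = exp(−Δ_i/2) / Σ_r exp(−Δ_r/2)`.
4. **Abundance-weighted population ogive** — area/season-specific predictions
   `p̂_las` from a discrete-latitude refit are combined with weights
   `W_las ∝ N_as · p_las · f_las` (relative abundance × length composition ×
   sex ratio), giving `P̂_ls = Σ_a W_las p̂_las` with
   `Var(P̂_ls) = Σ_a W²_las Var(p̂_las)` (weights treated as known).
5. **Synthetic-population generator** — an individual-based simulator with a
   latitudinal size gradient, set-clustered sampling, spawning migration and
   effort concentration on the spawning ground, used to validate every stage
   against known truth.

## Worked example

`python examples/04_weighted_ogive.py` simulates a large population
(~40 000 fish census, ~7 400 sampled females), fits the discrete-latitude
mixed model, derives abundance weights, and compares weighted and pooled
ogives:

```
season 1 (Oct-Mar):
  weighted   L50 = 85.55 cm, L100 = 108.0 cm
  unweighted L50 = 84.17 cm
season 2 (Apr-Sep):
  weighted   L50 = 85.30 cm, L100 = 108.0 cm
  unweighted L50 = 85.29 cm

true population L50 = 84.85 cm
```

In the spawning season the pooled ("unweighted") curve sits ~1.4 cm below
the weighted one — spawning-ground samples over-represent mature fish — while
in the off season the two agree; the weighted estimator tracks the known
population L50 in both seasons. The other examples cover histology
classification (`01`), the generator's mechanisms (`02`), and AICc model
selection with L50-by-latitude curves (`03`).

A thin CLI mirrors the library: `matogive simulate|classify|compare|ogive|run`
(see `matogive --help`), driven by a YAML config
(paths, latitude band edges, candidate-grid axes, seed).

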