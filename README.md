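# carmap

Bayesian spatial and spatio-temporal disease mapping for areal count
panels: BYM-type Poisson relative-risk models with intrinsic-CAR spatial
effects, an autoregressive space–time interaction, and quarterly seasonal
effects, fitted by an adaptive Metropolis-within-Gibbs sampler.

## The problem

Small-area surveillance data — here, suicide-related emergency calls per
census block group of a city, observed over years or trimesters — are too
sparse to map raw rates: most area–period cells hold zero or one event.
Disease mapping borrows strength across neighbouring areas and successive
periods to produce stable relative-risk estimates, a temporal trend, and
(at quarterly resolution) seasonal effects.  `carmap` implements the three
model layers such an analysis uses, in standard notation:

- **BYM spatial model**: `O_i ~ Poisson(E_i e^{η_i})`,
  `η_i = μ + φ_i + θ_i`, with `θ_i ~ N(0, σ_θ²)` iid and the ICAR prior
  `φ_i | φ_{−i} ~ N(mean of neighbours, σ_φ²/n_i)`;
- **autoregressive spatio-temporal model**:
  `η_i1 = μ + α_1 + (1−ρ²)^{−1/2}(φ_i1 + θ_i1)` and
  `η_it = μ + α_t + ρ(η_{i(t−1)} − μ − α_{t−1}) + φ_it + θ_it`,
  with a random-walk trend `α_t` and temporal correlation `ρ`;
- **quarterly seasonal extension**: adds fixed trimester effects `β_q(t)`
  (fourth trimester as reference, `β_4 = 0`), plus a `ρ = 0` variant used
  to show, via DIC, that the space–time interaction is worth its
  complexity.

Expected counts use internal standardization
(`E_i = pop_i × total events / total population`), so `exp(η)` is a
relative risk against the city-wide rate.  Because the motivating data are
confidential police records, the package ships a synthetic-study generator
that emulates their published shape (552 areas, populations 630–2845 with
mean ≈1334, 7 years / 28 trimesters, ≈6537 events, ≈70% zero cells at
quarterly resolution), and every experiment in the test suite runs on such
synthetic studies with known generative truth.

## Worked example

```python
import carmap
from carmap import DiseaseMapModel, McmcConfig

# a synthetic quarterly study at the published generative operating point:
# 15x15 lattice, 28 trimesters, truth = the motivating study's posterior means
study = carmap.generate_study("desk", seed=3)

model = DiseaseMapModel(study.panel, study.graph,
                        variant="st_quarterly", expected=study.expected)
result = model.fit(config=McmcConfig(n_chains=1, n_iter=3000, burn_in=800, seed=1))
print(result.summary().loc[["rho", "beta[3]", "sigma_theta"]].round(3))
print(result.dic())
```

prints (posterior mean, sd, 95% interval against generative truths
ρ = 0.903, β₃ = 0.118, σ_θ = 0.359):

```
              mean     sd   q2.5  q97.5
parameter
rho          0.905  0.008  0.888  0.919
beta[3]      0.094  0.059 -0.020  0.204
sigma_theta  0.356  0.017  0.330  0.394
DicResult(dic=10225.749297089511, mean_deviance=9462.543540507386, p_d=763.2057565821251)
```

The temporal correlation and the heterogeneity standard deviation come
back on top of their truths; the third-trimester seasonal effect is
recovered within its (data-limited) posterior uncertainty.  `result`
also exposes `temporal_effect()`, `seasonal_effect()` (with exp-scale rate
ratios against the reference trimester), `relative_risks()`,
`classify_trends()` (posterior classification of per-area trajectories),
`rhat()` / `ess()` diagnostics and line plots.

The same pipeline is scriptable from a shell:

```bash
carmap simulate --preset desk --seed 7 --out study/
carmap fit --counts study/counts.csv --populations study/populations.csv \
           --adjacency study/adjacency.gal --variant st_quarterly \
           --n-iter 5000 --burn-in 1000 --seed 1 --out fit/
carmap compare --counts study/counts.csv --populations study/populations.csv \
           --adjacency study/adjacency.gal \
           --variants st_quarterly,st_quarterly_rho0 --seed 1 --out cmp/
```

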