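# phitrend

Tools for analysing century-scale trends in the growth performance of
marine fishes, for fisheries scientists and quantitative ecologists working
with compilations of published von Bertalanffy growth curves.

Each published growth curve contributes an asymptotic total length L∞ (cm)
and growth coefficient K (yr⁻¹). Because the two trade off, the analysis
works on the growth-performance index

φ = log₁₀ K − S_L · log₁₀ L∞,   S_L = −(m·b) = −(0.761 × 3.03)

which standardises growth against body size (an empirical per-species S_L
from OLS regression is also supported). The package implements:

* **growth_metrics** — the closed-form φ algebra: length standardisation,
  constant and empirical S_L, Δφ, and the equivalence identities
  K_t/K_{t−1} = 10^Δφ (L∞ held) and L∞,t/L∞,t−1 = 10^(−Δφ/S_L) (K held)
  that re-express a φ change as a change in a single growth parameter.
* **covariates** — climate region from latitude (tropical ≤ 23°,
  subtropical ≤ 34°, temperate beyond), managed/unmanaged/unfished classes
  from family lists, and mean sea-surface temperature within a 2° buffer of
  each location on an annual 1°×1° raster (NetCDF or long CSV).
* **trend_model** — a Bayesian state-space model of the annual trend:
  gamma observations (shape τ, mean μ), log link over a latent random walk
  with drift plus family effects, a temperature slope, per-aging-method
  scalar offsets against the otolith baseline and per-method annual
  observation deviances. Derived quantities: per-year trend with credible
  ribbons, percent change between years, and K-/L∞-equivalent declines.
* **phylo_model** — a phylogenetic gamma GLMM of management × temperature
  effects with species/method/year random intercepts and a Brownian-motion
  phylogenetic effect built from any rooted newick chronogram.
* **synthetic_data** — generators with exactly the models' generative
  structure (plus ground-truth records and a Yule tree simulator) so every
  stage is testable end-to-end without downloads.
* **pipeline / CLI** — validated end-to-end runs with audited row
  filtering and deterministic, machine-readable reports.

Inference is an in-package adaptive Hamiltonian Monte Carlo sampler with
analytic gradients and exact interweaved recentering moves; convergence is
reported per parameter as split-chain R̂ and ESS with flags at R̂ < 1.01
and ESS > 1500. See `docs/methods.md` for the full model specifications,
priors, and design decisions.

## Worked example

Simulate a dataset with the default study-scale conditions (113-year span,
~800 observations, drift u = −0.00073 yr⁻¹ implied by a 7.9% decline),
fit the trend model, and re-express the fitted decline:

```python
import numpy as np
from phitrend import (SimulationDesign, simulate_trend_dataset,
                      StateSpaceConfig, fit)

data, table, truth = simulate_trend_dataset(SimulationDesign(), seed=42)
post = fit(data, StateSpaceConfig.test_scale(seed=42))

print(post.percent_change(1908, 2021))
print(post.equivalent_K_Linf_change(1908, 2021))
```

One run of this script prints (values rounded here for display):

```
{'median': 9.33, 'q05': 5.33, 'q95': 12.04}
{'K': {'median': 51.11, 'q05': 32.35, 'q95': 60.94},
 'L_inf': {'median': 26.68, 'q05': 15.59, 'q95': 33.48}}
```

The first line is the percent decline of the response-scale trend exp(x_t)
between 1908 and 2021 (median and 90% credible interval; positive numbers
are declines). The generator's drift implies a 7.9% *expected* decline;
this replicate's realised path, with its process noise, declined by 11.1%,
and the interval brackets it. The second line re-expresses the same posterior
change as the equivalent decline in K alone (holding L∞) and in L∞ alone
(holding K): a ~9% drop in growth performance at this baseline corresponds
to a ~51% decline in the growth coefficient or a ~27% decline in
asymptotic length.

The same fit carries the aging-method structure:

```python
print(np.median(post.scalar("mark_recapture")))   # 0.0519  (truth 0.05)
print(post.convergence_report().head(3))
```

(The desk-scale configuration keeps 900 draws, so the ESS > 1500 production
flag necessarily reports False there; use the default `StateSpaceConfig()`
— 4 chains × 6000/3000 — for converged production runs.)

From the shell, the equivalent pipeline run is:

```bash
phitrend simulate trend --out sim/ --seed 42
phitrend trend-fit --obs sim/observations.csv --out fit/ --group global --seed 42
```

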