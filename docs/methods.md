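# Methods

## The growth-performance index

Published growth curves for marine fishes report the von Bertalanffy
parameters L∞ (asymptotic total length, cm) and K (yr⁻¹, the rate of
approach to L∞). Because the two trade off strongly across populations,
neither is comparable on its own; the growth-performance index

φ = log₁₀ K − S_L · log₁₀ L∞

standardises the growth coefficient against body size. S_L is the slope
between log₁₀ L∞ and log₁₀ K. The package supports two forms:

* **constant** — S_L = −(m·b) with m = 0.761 (the mean metabolic scaling
  exponent for fishes, standing in for the anabolic exponent) and b = 3.03
  (the mean length–weight regression exponent), giving S_L = −2.30583;
* **empirical** — the OLS slope of log₁₀ K on log₁₀ L∞ per species, using
  every species × aging-method group with at least four observations
  ("more than three" read strictly). A species with qualifying groups under
  several methods gets the *median* slope across methods — a genuinely open
  design choice; the median is the robust default and the raw per-method
  slopes are exposed for users who want another rule.
  Degenerate groups (zero variance in log₁₀ L∞) and non-negative slopes are
  kept out of / in the result respectively, each with a logged warning.

A change Δφ = φ_t − φ_{t−1} can be re-expressed as an equivalent change in
a single parameter: K_t/K_{t−1} = 10^Δφ holding L∞, and
L∞,t/L∞,t−1 = 10^(−Δφ/S_L) holding K. These identities, exercised by the
acceptance script, connect the fitted trend to the familiar parameter
scales. The two ratios obey (K ratio)^(1/(m·b)) = L∞ ratio exactly.

Lengths reported as standard or fork length are converted to total length
with linear coefficients TL = a + b·length, resolved species-first, then
genus, then family; observations with no resolvable coefficients are
dropped with an audit reason, mirroring the exclusion of observations whose
parameters cannot be standardised.

## Covariates

* **Region** — tropical |lat| ≤ 23°, subtropical 23° < |lat| ≤ 34°,
  temperate beyond (poles included). The boundary values are assigned
  equatorward (±23 tropical, ±34 subtropical); the verbal band definitions
  are ambiguous at the boundary, so the closed-on-the-equatorward-side
  convention is adopted and tested explicitly.
* **Management class** — a family with a formal stock assessment is
  *managed*; one with reported or reconstructed catches but no assessment
  is *unmanaged*; all other families are *unfished*. Managed takes
  precedence; matching is case-insensitive. The two family lists are user
  inputs (one family per line, `#` comments).
* **SST** — the unweighted mean of all non-missing 1°×1° cells whose
  centres lie within 2 degrees (planar degree distance, longitude wrapped
  at ±180°) of the sampling location, for the sampling year. Whether the
  original buffer was circular or square, and whether cells were
  area-weighted, is a genuinely open choice; the circular unweighted mean
  in degree space is adopted, documented, and checked against a brute-force
  cell-enumeration oracle.
  Years absent from the raster raise an error naming the available span; an
  opt-in nearest-year mode exists for sparse rasters and always logs.

## State-space trend model

Each growth-performance value y_{i,t} is one observation of a single
underlying annual state. The observation layer is gamma with shape τ and
rate λ_{i,t} = τ/μ_{i,t} (so E y = μ, Var y = μ²/τ), with log link

log μ_{i,t} = α_{m(i),t} + α_fam(i) + β·X_i,
α_{m,t} = x_t + c_m + v_{m,t},   c_otolith = 0,
v_{m,t} ~ N(0, σ_{r,m}),

and the latent state is a random walk with drift,

x_t = x_{t−1} + u + w_t,  w_t ~ N(0, σ_q),  x_1 = x_0 + u + w_1.

The per-method scalars c_MR, c_OR, c_LF, c_UN absorb constant biases of
mark-recapture, other-ring, length-frequency and unknown aging relative to
the otolith baseline; the per-method σ_{r,m} let each method carry its own
annual observation deviance. Priors: τ ~ Gamma(0.01, 0.01), placed on the
shape because the rate λ = τ/μ is derived, not free — the shape is the only
free dispersion parameter; β ~ N(0, 2); x₀, u, scalars ~ N(0, 5);
σ_{r,m} ~ half-N(0, 1). Two prior scales are package decisions: σ_q ~
half-N(0, 1) (matching the σ_r prior) and hierarchical family effects
α_fam ~ N(0, σ_fam), σ_fam ~ half-N(0, 1).

Only (method, year) cells that contain observations carry an explicit
v_{m,t} parameter; empty cells contribute nothing to the likelihood and
integrate out of the posterior exactly.

**Reporting convention.** The trend is exp(x_t): the response-scale mean at
the reference cell — otolith method, family effect zero, SST centred at its
sample mean. Percent change between years a and b is 100·(1 − exp(x_b −
x_a)) per draw (positive = decline); the K- and L∞-equivalent declines
apply the ratio identities to the response-scale change Δφ = μ_b − μ_a per
draw. Intervals are the 5th/95th (and 25th/75th) percentiles of the
per-draw values; because the transforms are monotone, these equal the
transforms of the Δx quantiles up to interpolation between adjacent order
statistics (tested at 1e-6 on the percent scale).

Disaggregated fits (per management class, per region) are the same model
refit on filtered subsets; filtering is data-level. The temperature term is
included by default in every variant and can be disabled by flag.

## Phylogenetic gamma GLMM

Across observations i, y_i is gamma (shape τ, mean μ_i) with

log μ_i = β₀ + β_fish·x_fish + β_sst·x_sst + β_int·x_fish·x_sst
          + α_species + α_method + α_year + b_phylo.

Management is treatment-coded with *managed* as reference, so the managed
temperature slope is β_sst and the unmanaged/unfished slopes add their
interaction contrast; `slope_by_management` reports per-class slopes with
50%/90% intervals so the coding is invisible to users. Priors:
τ ~ Gamma(0.01, 0.01) (same shape-vs-rate convention as above);
β₀ ~ N(0, 5); the contrast coefficients ~ N(0, 2); all random-effect scales
half-N(0, 1) (package decision). SST is centred by default (package
decision).

b_phylo is a species-level effect with covariance σ²_phylo·C, where C is
the Brownian-motion correlation of a rooted, time-calibrated tree: entry
(i, j) is the shared root-to-MRCA path length scaled by the root-to-tip
depth (geometric mean of the two depths for non-ultrametric trees), unit
diagonal, positive semi-definite. Species random intercepts *and* the
phylogenetic effect are both retained; they are jointly identified only
through the correlation structure. Any resolved
newick tree is accepted; a grafting utility places missing species at their
genus MRCA with zero-length branches as a clearly-labelled synthetic
stand-in for proper stochastic polytomy resolution (which is out of scope).

## Inference

No probabilistic-programming backend is assumed: both models are fitted by
an in-package adaptive Hamiltonian Monte Carlo sampler over hand-derived
analytic gradients of the joint log density (gradients are verified against
finite differences in the test suite). The parameterisation is non-centred
throughout — innovations and random effects as standard-normal z-scores,
scales on the log with the Jacobian folded in — with a diagonal mass matrix
adapted over Stan-style expanding windows and dual-averaging step-size
adaptation (target acceptance 0.85), jittered trajectory lengths, and an
energy-error divergence threshold.

Two families of exact auxiliary Gibbs moves are interleaved with the HMC
transitions to handle posterior geometry a diagonal metric mixes through
only slowly:

* **shift moves** along likelihood-invariant directions — e.g. the drift u
  against the mean innovation, the intercept against each random-effect
  block (for the phylogenetic block, through L⁻¹1) — whose conditionals are
  Gaussian because the latent path/fitted means are unchanged;
* **scale moves** in centred coordinates — holding the centred effects
  w = σ·z fixed, the conditional of a half-normal scale is generalized
  inverse Gaussian in σ², updated by a slice-sampling step.

Both are standard interweaving strategies; each leaves the exact posterior
invariant, and the composition with HMC is a valid kernel. Without them the
effective sample size of u and of the variance components collapses to
single digits at desk scale.

Convergence is summarised per monitored parameter by split-chain
rank-normalised R̂ and bulk ESS (via arviz) with pass flags at R̂ < 1.01
and ESS > 1500. A fit that fails either flag is still returned, marked
`converged=False`. The production defaults are 4 chains × 6000/3000 for
the trend model and 4 × 4000/2000 for the GLMM;
`*.test_scale()` configures 2 chains at reduced length (trend 900/450,
GLMM 700/350) for desk-scale recovery work. At desk scale the ESS > 1500 flag is unattainable by
construction (fewer than 1500 total draws are kept) — the flag reports
honestly; tests assert on recovery, not on the flag.

## Synthetic data

The generators draw from exactly the generative structure the two models
assume, returning a `SyntheticTruth` record so recovery tests close the
simulate → fit → recover loop. Default design: 1908–2021, five aging
methods dominated by otoliths (55%), management mix 55/30/15
managed/unmanaged/unfished assigned at the family level, a triangular
sampling-intensity ramp rising from 1950 to a 2005 peak and declining after
2010 (the exact ramp shape is cosmetic), and an SST field with a smooth
poleward-cooling profile plus a +1 °C linear trend across the span —
matching the roughly one-degree warming over the study period — plus noise
and an optional land mask.

Default generative parameters: drift u = −0.00073 yr⁻¹ (the value implied
by a 7.9% response-scale decline over 113 annual steps), x₀ = log 3.3 (the
1908 median), σ_q = 0.004, per-method σ_r between 0.02 and 0.05, method
scalars up to 0.05 in magnitude, τ = 200 (≈7% observation CV, a realism
choice), β = 0.02 per °C, family effect scale 0.08. The GLMM generator
defaults to per-class temperature slopes of −0.00011, 0.023 and 0.040 for
managed/unmanaged/unfished, species and phylogenetic effect scales 0.08, and a Yule
tree (unit depth) simulated by the standard forward construction.

Default scale is ~10% of the real compilation (150 species, 800
observations) so the full recovery suite runs in minutes on one CPU; the
recovery tests use 20 replicates at that scale for interval coverage of u
and β, one n = 2000 fit for method-scalar recovery, and 10 replicates at
n = 3000 for the GLMM slope bias. These sizes are the package's test-scale
choices; the generators take the full scale as ordinary parameters.

**What the generators do not emulate:** real taxonomic composition and
shared species across families; spatial autocorrelation of sampling
locations; correlation between management class and latitude (each is
drawn independently); reporting error in published L∞/K beyond the gamma
layer; the compositional-shift (ordination) analyses. Passing recovery
tests therefore demonstrates that the estimators are correct under the
models' own assumptions — not that those assumptions hold for any
particular real compilation.

## Numerical choices and edge cases

* Gamma log densities are computed with explicit normalising constants, so
  `log_density` is the exact joint density, not a proportional one.
* Out-of-support or absurd parameter values (non-finite, |θ| > 50 on the
  unconstrained scale, |log μ| > 500) yield −∞, never an exception.
* Cholesky of a phylogenetic correlation adds a 1e-9 jitter and falls back
  to an eigenvalue clip at 1e-9 for numerically non-PSD input.
* Newick labels are compared with underscores and spaces identified, as
  newick readers conventionally interconvert them.
* Ties at region boundaries go to the equatorward band; latitudes outside
  [−90, 90] are rejected.
* All randomness flows from `numpy.random.SeedSequence`: one root seed per
  fit or pipeline run, spawned per chain/stage; repeated runs are
  bit-identical.

## Known limitations

* The diagonal-metric HMC with interweaving is adequate for these two
  models but is not a general-purpose NUTS; heavy-tailed or strongly
  multimodal posteriors are out of scope.
* σ_q and the σ_r's are only weakly separated at desk-scale sample sizes
  (few observations per method-year cell); their posteriors are honest but
  wide, and the desk-scale convergence flag is expected to fail for them.
* The pairwise-normalised correlation for non-ultrametric trees is a
  pragmatic convention; for seriously non-ultrametric trees a proper
  evolutionary model should be fitted instead.
* `graft_missing_species` encodes taxonomy, not inferred divergence times;
  it exists so a partial tree can cover an observation table, nothing more.
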