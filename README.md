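# metapatch

Noise-driven host-parasitoid metapopulation dynamics: stochastic simulation,
hierarchical time-lagged Ricker inference, and spatial asynchrony
diagnostics.

## The problem

In small, patchy metapopulations — a handful of habitat patches, low
abundances — population fluctuations are dominated by noise rather than by
deterministic cycles or chaos. Whether such a metapopulation persists
regionally depends on how synchronous the local fluctuations are: patches
that fluctuate out of phase can rescue each other, patches in phase crash
together. This package implements, as a tested pipeline, the two halves of
that question for laboratory-scale host-parasitoid systems (bruchid beetles
and a pteromalid parasitoid in four-patch square-lattice microcosms):

1. a **mechanistic simulator** asking how host and parasitoid dispersal
   shape spatial correlation and extinction risk, and
2. a **statistical inference layer** estimating local density dependence and
   patchwise spatial correlation from weekly count series.

## The models

**Simulation.** Local dynamics are a discrete-time Nicholson-Bailey map with
a host carry-over term and multiplicative environmental noise:

    H' = R ε H e^{−aP} + S H,    P' = c H (1 − e^{−aP}),

with `ε` lognormal and mean one, independent across patches and steps.
A fixed fraction `S` of hosts escapes parasitism, which stabilises the
otherwise divergent Nicholson-Bailey equilibrium: at the default parameters
(R = 2.718, a = 0.1, S = 0.7, c = 1) the spectral radius at the equilibrium
is 0.967, so fluctuations are purely noise-driven. Patches exchange fixed
proportions `dH`, `dP` of hosts and parasitoids per step. Occupancy
statistics (sub-threshold events, regional persistence times) and
dispersal-correlation surfaces quantify extinction risk; a Ricker-logistic,
parasitoid-free null model provides the contrast between trophic and direct
density dependence. See `docs/methods.md` for every modelling choice.

**Inference.** Weekly net reproductive rate `r_t = ln(N_{t+1}/N_t)` is
regressed on Box-Cox-transformed abundances lagged by τ weeks (half-week
lags by interpolation, θ optimized per lagged series):

    r_t = α + Σ_k β_k x_{t−τ_k} + (replicate) + (patch) + ε_{i,j,t},

a hierarchical model with patches nested in replicate metapopulations and
residuals of the patches of one replicate in the same week exchangeable with
correlation ρ — the patchwise spatial correlation, negative under
asynchrony. Estimation is by maximum likelihood (statsmodels-style
`LaggedRickerModel.fit()` → `LaggedRickerResults`); lag structures are
compared by AIC weights and evidence ratios. Distance-resolved asynchrony is
checked with weekly empirical semivariograms γ(1) vs γ(2) on the square
lattice and paired Wilcoxon tests. Because the original microcosm counts
are not distributed, a synthetic-data module generates datasets with the
assumed statistical structure (and serialized ground truth) for validation.

## Worked example

```python
import metapatch as mp

params = mp.NBParams()                      # R=2.718, a=0.1, S=0.7, c=1
H, P = mp.nb_equilibrium(params)
print(f"equilibrium: H* = {H:.2f}, P* = {P:.2f}")
print(f"spectral radius: {mp.local_stability(params):.3f}")

truth = mp.RickerTruth(alpha=0.5, betas=(-0.02,), lags=(1.0,), thetas=(1.0,),
                       rho=-0.06, sigma_replicate=0.0, sigma_patch=0.0,
                       sigma_error=0.2)
series, _ = mp.generate_from_ricker(truth, n_replicates=4, n_patches=4,
                                    n_weeks=60, seed=1)
dataset = mp.build_dataset(series, mp.LagSpec(lags=(1.0,), thetas=(1.0,)))
result = mp.fit_hierarchical(dataset)
print(result.summary())
```

prints

```
equilibrium: H* = 24.77, P* = 22.04
spectral radius: 0.967
Hierarchical time-lagged Ricker model (ML)
==========================================================
n_obs: 928   log-likelihood: 167.1567   AIC: -322.3135
free parameters: 6   converged: True
----------------------------------------------------------
term              estimate     std err    [0.025    0.975]
intercept           0.5141      0.0213    0.4723    0.5559
lag_1              -0.0204      0.0008   -0.0219   -0.0188
----------------------------------------------------------
sigma_replicate: 0.0000   sigma_patch: 0.0000   sigma_error: 0.2023
patchwise spatial correlation rho: -0.0338 (SE 0.0249)
flags: sigma_replicate at boundary (~0); sigma_patch at boundary (~0)
```

The host equilibrium sits just below 25 animals per patch with damped
oscillations. The fit recovers the generating intercept (α = 0.5), the
negative one-week density dependence (β = −0.02, i.e. growth falls as last
week's abundance rises) and the residual scale; the estimated patchwise
correlation ρ̂ = −0.034 ± 0.025 is consistent with the generating −0.06
(mildly asynchronous patches), and the unused variance components are
correctly flagged at the zero boundary.

A command-line interface mirrors the library:

```sh
metapatch --seed 1 --out-dir out generate --mode mechanistic --treatment b
metapatch --seed 1 --out-dir out fit out/series.csv --lags "1;3.5;1,3.5"
metapatch --seed 1 --out-dir out semivariogram out/series.csv
metapatch --seed 1 --out-dir out pipeline
```

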