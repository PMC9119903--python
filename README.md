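# graylinggrowth

Stage-specific growth and abundance modelling for riverine European
grayling (*Thymallus thymallus*) — and, more generally, for any
age-structured fish population monitored by multi-pass depletion
electrofishing with annual environmental covariates.

The package is aimed at fisheries and population ecologists who want to ask:
*which abiotic and biotic conditions — temperature, flow extremes, prey,
habitat, intra- and inter-specific competitor density — drive year-to-year
variation in length-at-age, and do those drivers differ between juvenile,
sub-adult and adult life stages?*

## The models

**Abundance.** Each survey unit (year *y*, site *s*, age/size-class *a*) has
latent abundance and a depletion observation layer with per-group capture
probability *p₉*:

```
N[y,s,a] ~ Poisson(λ[y,s,a]),   log λ[y,s,a] = α[y,s,a]
C₁ ~ Binomial(p_g, N)
C₂ ~ Binomial(p_g, N − C₁)
C₃ ~ Binomial(p_g, N − C₁ − C₂)
```

Single-pass years enter the same joint model (k = 1) and share *p₉*.
Posterior mean abundances become the stage- and site-specific competitor
covariates of the growth model.

**Growth.** Expected juvenile (age 0+) fork length is a von Bertalanffy
length-at-age scaled by a log-linear covariate term, and older age-classes
grow by a Fabens-style increment whose size is scaled the same way:

```
μ[y,s,1]   = L∞ (1 − e^{−K(t₁−t₀)}) · exp(θ₁·X[y,s,1])
μ[y+1,s,a] = μ[y,s,a−1] + (L∞ − μ[y,s,a−1]) (1 − e^{−K(t_a−t₀)}) · exp(θ_l·X[y+1,s,l])
L_i ~ Normal(μ[y,s,a], σ)
```

with life stages l = 1 (age 0+), 2 (age 1+), 3 (ages 2+–5+), t_a = a, and
z-standardised covariates X so that coefficients are comparable across
variables. Setting every covariate to its mean reduces the model exactly to
the deterministic von Bertalanffy recursion.

Covariate sets are simplified stage by stage (juvenile → sub-adult → adult)
by iteratively removing coefficients whose 95% credible interval straddles
zero, and the resulting "full model" is verified against candidate models by
PSIS-LOO (Pareto-smoothed importance-sampling leave-one-out
cross-validation, re-implemented here with the Pareto-k diagnostic).

Inference is Metropolis-within-Gibbs MCMC written for this package: exact
conjugate updates for L∞, the observation precision, the first-year expected
lengths and the capture probabilities, adaptive block random-walk Metropolis
for the rest, with classic Gelman–Rubin R-hat (< 1.1) convergence checks.
The growth kernel is numba-compiled so the many refits of the
simplification procedure stay cheap.

A first-class synthetic-data module generates complete study-shaped datasets
(17 years × 6 sites, daily temperature and discharge series, annual habitat
indices, depletion catches, ~5,600 length records) with known truth, so the
entire pipeline is testable without any field data.

## Worked example

Estimating abundance from one depletion unit with catches 50, 25, 12
(`examples/02_depletion_abundance.py`):

```
total catch            : 87
posterior abundance N  : 101.1  95% CrI [90, 124]
capture probability p  : 0.495  95% CrI [0.343, 0.616]
converged (R-hat < 1.1): True
```

The declining catches imply p ≈ 0.5 per pass, so about one fish in eight
escaped all three passes — the model estimates ~14 unseen fish beyond the
87 caught. On this unit an exhaustive grid posterior (N ∈ [87, 600] × 999
p-values, α marginalised numerically) gives E[N] = 101.4, matching the MCMC
answer within Monte-Carlo error.

Fitting the growth model to a synthetic study simulated at
L∞ = 350 mm, K = 0.15 /yr, t₀ = −2 yr, σ = 15 mm
(`examples/03_growth_fit.py`):

```
core growth parameters (truth: L_inf=350, K=0.15, t0=-2, sigma=15):
              mean     sd     lo95     hi95   rhat
Linf       350.581  2.022  346.688  354.885  0.999
K            0.151  0.012    0.128    0.173  0.999
t0          -1.987  0.233   -2.517   -1.598  0.999
sigma       14.686  0.368   14.010   15.486  1.001
```

All four truth values sit inside their 95% credible intervals. The same
script prints the post-hoc ordinary-least-squares year trend of expected
length at age and a marginal-effect curve — e.g. juvenile expected length
rising from 115.5 mm to 139.4 mm across ±2 sd of growing-season mean
temperature, the analogue of holding every other retained variable at its
mean.

`examples/01_simulate_study.py` shows the full synthetic study bundle and
`examples/04_model_selection.py` runs the staged simplification: with two
pure-noise covariates injected per stage, it removes the noise variables and
retains the true effects, and no candidate full model beats the simplified
model by more than one elpd standard error.

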