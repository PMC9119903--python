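# Methods

This note documents the statistical models implemented in `graylinggrowth`,
the numerical choices behind the samplers, what the synthetic-data generator
does and does not emulate, and the design decisions taken where the
methodology was genuinely open.

## Depletion N-mixture abundance model

Each survey unit (year × site × class) has latent integer abundance
`N ~ Poisson(λ)`, `log λ = α`, `α ~ Normal(0, sd 10)` (a weakly informative
prior on the log scale: ±2 sd spans e⁻²⁰ to e⁺²⁰ fish). The observation
layer is the sequential depletion series `C_j ~ Binomial(p_g, N − Σ_{i<j}
C_i)` with `p_g ~ Beta(1, 1)` shared across units within a capture group
(grayling: age 0+ separately from ages 1+–5+; trout: one group). Units
fished with a single pass are k = 1 rows of the same joint model and
contribute to the shared `p_g` through their first-pass catch.

Two structural facts make the sampler exact and fast:

* conditional on `α` and `p`, the never-caught remainder is Poisson-thinned,
  so `N | C, α, p = total catch + Poisson(λ(1−p)^k)` — an exact draw that
  implicitly truncates `N` at the observed total and explores the entire
  upper tail (no explicit truncation bound is needed);
* conditional on `N` and the catches, `p_g` is conjugate:
  `Beta(1 + Σ catches, 1 + Σ escapes)` where escapes sum `N − cumulative
  catch` over passes.

Only `α | N` needs Metropolis (vectorised random-walk across units, step
sizes adapted during burn-in toward 44% acceptance and frozen afterwards).
Defaults follow the study design: 3 chains × 30,000 iterations, 10,000
burn-in, thin 100. On a single unit with catches (50, 25, 12) the posterior
means match an exhaustive grid posterior (N × p grid with α marginalised by
quadrature) within Monte-Carlo error; this is a standing acceptance test.

## Stage-covariate growth model

Fork length of fish *i* in year *y*, site *s*, age-class *a* (1..6 coding
ages 0+..5+) is `L_i ~ Normal(μ[y,s,a], σ)`. Expected lengths follow a von
Bertalanffy curve whose *increments* are scaled by stage-specific log-linear
covariate effects (see README for the equations), with `t_a = a`: the
age-class index is the age value that makes the published parameter point
(L∞ = 347.61, K = 0.14, t₀ = −2.27) reproduce the published length scales
(≈127.7 mm at 0+, ≈226.7 at 1+, ≈289.8 at 2+). The update equation is
implemented in the Fabens increment form `μ_prev + (L∞ − μ_prev)(1 −
e^{−K(t_a−t₀)})·e^{θ·x}`; a `literal_form` flag provides the non-incremented
variant `(L∞ − μ_prev)(…)·e^{θ·x}` for comparison — at the published
parameter point that variant yields 99 mm at age 1+, far off the published
scale, which is why the increment form is the default.

Cohort chains run through the recursion `μ[y+1,s,a] ← μ[y,s,a−1]`; chains
that would need years before the study frame anchor on free first-year
parameters `μ_init[s,a]` (ages 2..6 in year 1). Expected length is a
property of (year, site, age), not of individuals, so all fish in a cell
share a mean.

### Priors

JAGS-style mean/precision notation throughout; configurable via
`GrowthPriors`. Defaults: `K ~ Gamma(1, 1)`, observation precision
`τ = σ⁻² ~ Gamma(0.01, 0.01)`, `t₀ ~ Normal(0, prec 0.001)` (sd ≈ 31.6
years — weak for a parameter near −2), coefficient vectors
`θ ~ Normal(0, prec 0.001)` (weak for effects of order 0.05 on the
standardised scale). For the millimetre-scale location parameters — L∞ and
the first-year expected lengths — a zero-centred precision-0.001 Normal
(sd 31.6 mm) is *not* weak: it shrinks 200–350 mm quantities by tens of mm,
and in simulation recovery that bias propagates into K (+20%) and t₀
(+0.5 yr) and inflates σ. Their default precision is therefore 1e-6
(sd 1000 mm), the conventional vague setting;
`GrowthPriors.notation_literal()` restores the uniform precision-0.001
reading for anyone wanting the literal notation everywhere.

### Sampler

Metropolis-within-Gibbs, numba-compiled:

* **Exact Gibbs** for L∞ (every cell mean is affine in L∞, so
  Normal-likelihood + Normal prior is conjugate; the affine coefficients
  come from two recursion passes at L∞ = 0 and 1), for τ (conjugate Gamma),
  and for each `μ_init[s,a]` (along a cohort the recursion is affine in its
  starting value with multiplier `1 − G·E` per step, so all downstream
  cells combine conjugately with the prior).
* **Adaptive block random-walk Metropolis** for (log K, t₀) — jointly,
  with an empirical-covariance proposal (Haario-style) and a global scale
  adapted toward 23.4% acceptance, both frozen at the end of burn-in — and
  for each stage's θ vector as one block. The (log K, t₀) block sits on a
  narrow curved ridge and mixes slowest, so it receives four sub-updates
  per sweep (each is a single cheap likelihood evaluation).

K is sampled as log K and τ as log τ with the appropriate Jacobians.
Chains are initialised from a data-informed heuristic — a coarse
grid-plus-least-squares von Bertalanffy fit to pooled age means, pooled
within-cell sd for σ, observed first-year cell means for μ_init — jittered
per chain so the three chains start overdispersed. Initialising from the
vague priors themselves would put chains thousands of mm from the data and
make short runs meaningless; the generic sampler in `mcmc.run_mcmc` still
supports prior-draw initialisation for models whose priors are informative
enough to be sensible starting distributions.

The likelihood is evaluated from per-cell sufficient statistics (count,
sum, sum of squares), so its cost is independent of the number of fish.
Pointwise per-record log-likelihoods (for LOO) are evaluated only on the
retained draws.

Default run length mirrors the study: 3 × 30,000 / 20,000 / 100. The
reduced settings used in tests (3 × 6,000 / 3,000 / 10 for recovery,
3 × 2,500 / 1,250 / 10 inside the simplification loop) were chosen as the
smallest runs at which the Gelman–Rubin diagnostic is routinely < 1.1 for
every parameter on study-shaped data; they are problem-size choices, and
all production defaults remain the full-length runs.

## Diagnostics

`gelman_rubin` implements the classic (non-split) potential scale reduction
factor `sqrt((n−1)/n + B/(nW))`, matching the diagnostic's original
formulation; a `split=True` option halves each chain first and catches
within-chain drift. Convergence is declared at R-hat < 1.1 for every
parameter; non-convergence sets a flag on the result rather than failing
silently. Summaries are posterior means and equal-tailed 2.5/97.5%
intervals with linear-interpolation quantiles — the same quantile
convention used for the flow thresholds.

## Covariates

Seasonal windows are closed civil-calendar date intervals: growing season
1 April – 30 September of year *y*; autumn–winter 1 October of *y*−1 –
31 March of *y* (leap days included). Hot days use a strict `> 20 °C`
comparison ("exceeded"); low-/high-flow days use inclusive `≤ Q90` / `≥ Q10`
comparisons, where Q90/Q10 are the empirical 10th/90th percentiles (linear
interpolation) of all daily discharges across the study period. Missing
daily values may be imputed by a date-join from a donor gauging series
before any window statistic is computed.

Standardisation is z-scoring per variable over its distinct (year, site)
support — so a year-level variable replicated across six sites is not
over-weighted — with means and sds stored for back-transforming
marginal-effect axes. The collinearity screen computes pairwise Pearson
correlations within each life stage's variable set and flags |r| ≥ 0.7.
Which member of a flagged pair to keep is an ecological judgement, so an
unresolved pair is an error by default; the shipped default drop list
removes the hot-day count in favour of mean growing-season temperature.
For simulation studies, where flagged pairs are sampling accidents of a
17-point annual series, `resolve="drop_second"` applies a mechanical rule
instead.

Macrophyte cover and the macroinvertebrate biomass index are accepted as
annual year-level values replicated across sites: the underlying monitoring
programmes are separate from the fish survey and site-level resolution is
not available.

## Model simplification and LOO

Stages are simplified in order juvenile → sub-adult → adult; while a stage
is under simplification, later stages' covariates are omitted entirely.
Removal is one variable per refit — the coefficient whose 95% interval most
centrally straddles zero (smallest |mean|/sd) — chosen as the conservative
reading of "removing variables whose effect intercepted zero"; a batch mode
removes all straddling variables per refit. Fit seeds derive
deterministically from a master seed and the lineage position, so a
simplification run is exactly reproducible. A non-converged inner fit
records a warning note on the model spec and continues by default
(`on_nonconvergence="abort"` raises instead, carrying the lineage so far);
a single spurious R-hat excursion on a nuisance parameter should not
discard an entire staged run.

Candidate full models re-add the last-removed variable for each stage.
Comparison uses PSIS-LOO implemented from the published algorithm: raw
importance ratios 1/p(yᵢ|draw); the largest ceil(min(0.2·S, 3√S)) ratios
replaced by expected order statistics of a generalised Pareto distribution
fitted to the exceedances (Zhang–Stephens profile posterior-mean estimator
with the standard small-sample shape regularisation), truncated at the raw
maximum; elpd per observation from the normalised smoothed weights;
Pareto-k reported per observation with a warning flag when more than 10%
exceed 0.7. The implementation is cross-checked against `arviz.loo` in the
test suite, and against brute-force leave-one-out refitting on a small
fixture. Selection takes the lowest LOOIC, with any model within one
standard error (of the pointwise elpd difference against the best) counted
as tied and ties resolved toward fewer coefficients.

The exact-LOO acceptance fixture deserves a note: importance sampling
approximates case deletion badly when a single observation dominates a
parameter, which in this model happens for observations in sparsely
populated first-year cells whose `μ_init` has a vague prior. The fixture
therefore samples ages 0+–1+ over a 5-year × 2-site frame and drops
first-year age-1+ records, so every populated cell is informed through the
juvenile-anchored recursion and Pareto-k stays below 0.7. That is the
regime in which PSIS is designed to work; the k diagnostic is precisely the
tool that flags the other regime.

## Synthetic-data generator

The generator reproduces the study's statistical *structure*, with every
default chosen once as a realistic operating point:

* **Frame**: 17 years × 6 sites, grayling age-classes 0+–5+, two trout
  size-classes; single-pass sampling in the first six years, three-pass
  depletion thereafter.
* **Environment**: daily temperature = seasonal sinusoid (mean 10.5 °C,
  amplitude 6.8 °C, peak mid-July) + Gaussian noise (sd 2.2 °C), no trend by
  default; daily discharge = lognormal around a seasonal baseflow curve
  with AR(1) log-noise and a small positive log-trend (+0.012/yr), which
  makes low-flow days decline over the series; annual macrophyte cover
  (mean 40%, no trend) and invertebrate biomass (declining 2.5 index
  units/yr). These defaults mimic the monitored river's qualitative trends:
  declining low-flow days and invertebrate biomass, stable temperature.
* **Abundance**: per-class mean abundances decline with age (60 → 3.5 per
  site across ages 0+–5+), adult classes decline over years (−4.5%/yr),
  juvenile trout increase (+5%/yr); fixed lognormal site effects (sd 0.30)
  and year-to-year lognormal noise (sd 0.25); capture probabilities 0.5
  (age 0+), 0.6 (older grayling and trout). Catches are sequential binomial
  thinning of Poisson abundances.
* **Lengths**: expected lengths from the growth recursion at truth
  L∞ = 350 mm, K = 0.14, t₀ = −2.3, near the published estimates, with
  first-year older-age expectations on the deterministic baseline chain;
  truth coefficients mirror the retained-variable sign structure of the
  final model (magnitudes 0.03–0.06 on the standardised scale, sized so
  that e.g. the temperature effect spans the published 124→140 mm juvenile
  range); Normal observation error sd 15 mm; ~5,600 records with an
  age-frequency profile declining from 34% (age 0+) to 4% (age 5+); 15.23%
  flagged as recaptures (853 of 5,602).

What the generator does **not** emulate — and hence what passing recovery
tests cannot certify about real data: sub-annual growth variation and
sampling-date jitter, individual growth heterogeneity and size-dependent
capture, ageing error from scale reading, spatial correlation between
sites, temperature–discharge dependence, and any model misspecification
(the generator draws from exactly the fitted model family). Recovery
results show the estimator works when its assumptions hold; they cannot
show the assumptions hold in the field.

## Degenerate inputs and numerical edges

Constant covariate columns are a standardisation error (zero variance);
constant discharge series collapse Q90 = Q10 with a warning; empty seasonal
windows raise with the offending year named; depletion pools that would go
negative give log-likelihood −∞; identical chains make R-hat raise
(degenerate variance) rather than return 1; growth ingestion rejects
age-classes outside 1..6 (file readers drop ages 6+/7+ with a warning,
since growth is not estimated for them, and reject anything else outside
the frame). All quantile computations share the linear-interpolation
convention. Seeds are mandatory for every stochastic entry point; chain *c*
derives its generator from `seed + c`, and simplification fit seeds derive
from the master seed and lineage position.

## Known limitations

* The growth model assumes a single observation-error scale σ across ages;
  length variability plausibly grows with age.
* No sex-, maturation- or individual-level growth structure (recaptures are
  handled only by the exclusion sensitivity check).
* Abundance units are independent across years and sites — no spatial or
  temporal smoothing of λ, and no covariates on abundance itself.
* The classic R-hat can miss within-chain drift; the split variant is
  available but not the default, to match the diagnostic's original
  formulation.
* PSIS-LOO is unreliable (and says so via Pareto-k) for observations that
  dominate a vaguely-informed local parameter, e.g. lone fish in first-year
  cells.
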