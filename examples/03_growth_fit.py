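"""Fit the stage-covariate growth model to a synthetic study and summarise.

Simulates a reduced study (10 years x 3 sites, ~900 lengths) from known
truth (L_inf = 350 mm, K = 0.15, t0 = -2), fits the model by MCMC, then
prints the core growth parameters, the post-hoc year trend in expected
length at age, and one marginal-effect curve.
"""

import numpy as np

from graylinggrowth import GrowthParams, fit_growth
from graylinggrowth.growth import expected_length_series, marginal_effect
from graylinggrowth.mcmc import McmcSettings
from graylinggrowth.simulate import SyntheticTruth, simulate_study

truth = SyntheticTruth(n_years=10, n_sites=3, total_lengths=900)
truth.growth = GrowthParams(linf=350.0, k=0.15, t0=-2.0, sigma=15.0)
study = simulate_study(truth, seed=17)

post = fit_growth(
    study["lengths"],
    study["covariates"],
    settings=McmcSettings(chains=3, iterations=6000, burn_in=3000, thin=10, seed=5),
)

print("core growth parameters (truth: L_inf=350, K=0.15, t0=-2, sigma=15):")
print(post.summary.loc[["Linf", "K", "t0", "sigma"]].round(3))
print(f"\nall R-hat < 1.1: {post.converged}")

series, trend = expected_length_series(post)
print("\nOLS year slope of site-averaged expected length (mm/year):")
print(trend.round(3).to_string(index=False))

table = study["covariates"]
var = "meanT_SA"
mean, sd = table.scales[var]
grid = np.linspace(mean - 2 * sd, mean + 2 * sd, 5)
curve = marginal_effect(post, table, var, stage=1, grid=grid)
print(f"\nmarginal effect of {var} on juvenile expected length (mm):")
print(curve.round(2).to_string(index=False))
print("\nA positive coefficient shows as a rising curve: warmer growing")
print("seasons mean longer age-0+ fish, all else held at its mean.")
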