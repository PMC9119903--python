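"""Estimate abundance from 3-pass depletion electrofishing catches.

A single survey unit caught 50, 25 and 12 fish on successive passes
(87 in total).  The N-mixture model treats true abundance N as latent
Poisson and each pass as a binomial draw from the fish still present, so
it estimates how many fish were never caught.
"""

import pandas as pd

from graylinggrowth import fit_abundance
from graylinggrowth.mcmc import McmcSettings

catches = pd.DataFrame(
    {
        "year": 2010,
        "site": 1,
        "cls": 1,
        "pass_idx": [1, 2, 3],
        "count": [50, 25, 12],
    }
)

est = fit_abundance(
    catches,
    groups={1: 1},
    settings=McmcSettings(chains=3, iterations=30_000, burn_in=10_000, thin=100, seed=5),
)

row = est.table.iloc[0]
p = est.p_summary.iloc[0]
print(f"total catch            : 87")
print(f"posterior abundance N  : {row['mean']:.1f}  95% CrI [{row['lo95']:.0f}, {row['hi95']:.0f}]")
print(f"capture probability p  : {p['mean']:.3f}  95% CrI [{p['lo95']:.3f}, {p['hi95']:.3f}]")
print(f"converged (R-hat < 1.1): {est.converged}")
print("\nThe declining catches (50 -> 25 -> 12) imply p ~ 0.5 per pass, so")
print("roughly one fish in eight was never seen: N is estimated above 87.")
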