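import warnings

import numpy as np
import pandas as pd
import pytest

import graylinggrowth as gg
from graylinggrowth.mcmc import McmcSettings
from graylinggrowth.simulate import SyntheticTruth, simulate_study

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def published_params() -> gg.GrowthParams:
    """Growth parameters at the published posterior means."""
    return gg.GrowthParams(linf=347.61, k=0.14, t0=-2.27, sigma=10.0)


@pytest.fixture(scope="session")
def small_study() -> dict:
    """A reduced synthetic study (10 years x 3 sites, ~900 lengths)."""
    truth = SyntheticTruth(n_years=10, n_sites=3, total_lengths=900)
    truth.growth = gg.GrowthParams(linf=350.0, k=0.15, t0=-2.0, sigma=15.0)
    return simulate_study(truth, seed=17)


@pytest.fixture(scope="session")
def small_fit(small_study) -> gg.PosteriorResult:
    """One converged growth fit on the reduced study."""
    return gg.fit_growth(
        small_study["lengths"],
        small_study["covariates"],
        settings=McmcSettings(3, 4000, 2000, 10, seed=5),
    )


@pytest.fixture
def daily_temp() -> gg.DailySeries:
    """Two calendar years of synthetic daily temperature."""
    idx = pd.date_range("2009-10-01", "2011-12-31", freq="D")
    doy = idx.dayofyear.to_numpy(dtype=float)
    vals = 10.0 + 7.0 * np.cos(2 * np.pi * (doy - 196) / 365.25)
    return gg.DailySeries(pd.Series(vals, index=idx), kind="temperature")
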