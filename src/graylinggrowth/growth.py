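"""Stage-specific von Bertalanffy growth model for length-at-age.

Expected juvenile (age 0+, age-class a=1) length in year y and site s:

    mu[y,s,1] = L_inf * (1 - exp(-K (t_1 - t0))) * exp(theta_1 . X[y,s,1])

Older age-classes grow by a Fabens-style increment on the previous
age-class's expected length, with the increment scaled by the stage's
covariate multiplier:

    mu[y+1,s,a] = mu[y,s,a-1]
                  + (L_inf - mu[y,s,a-1]) * (1 - exp(-K (t_a - t0)))
                  * exp(theta_l . X[y+1,s,l])

with t_a = a (age-class index) and life stage l = 2 for age-class 2,
l = 3 for age-classes 3..6.  Setting every covariate to its mean
(standardised 0) reduces the model to the plain von Bertalanffy recursion.
A ``literal_form`` flag drops the leading ``mu_prev +`` term for comparison
with the non-incremented variant of the update equation.

Individual fork lengths are modelled as Normal(mu[y,s,a], sigma) with
sigma = tau**-0.5 and a Gamma prior on the precision tau.  First-year
expected lengths of age-classes 2..6 are free parameters so that cohort
chains anchoring before the study frame remain estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _growth_kernel as gk
from .covariates import CovariateTable
from .mcmc import McmcSettings, PosteriorResult
from scipy.optimize import minimize

__all__ = [
    "AGE_TO_STAGE",
    "GrowthParams",
    "GrowthPriors",
    "juvenile_expected_length",
    "update_expected_length",
    "baseline_lengths",
    "growth_loglik",
    "fit_growth",
    "expected_length_series",
    "marginal_effect",
]

#: age-class a (1..6 = ages 0+..5+) -> life stage l (1 juvenile,
#: 2 sub-adult, 3 adult)
AGE_TO_STAGE: dict[int, int] = {1: 1, 2: 2, 3: 3, 4: 3, 5: 3, 6: 3}
N_AGES = 6


@dataclass
class GrowthParams:
    """Growth-model parameters on their natural scale.

    ``theta`` maps stage -> coefficient vector (standardised-covariate
    scale); ``mu_init`` is the (n_sites, 5) array of first-year expected
    lengths for age-classes 2..6.
    """

    linf: float
    k: float
    t0: float
    sigma: float = 15.0
    theta: dict[int, np.ndarray] = field(default_factory=dict)
    mu_init: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.linf <= 0 or self.k <= 0 or self.sigma <= 0:
            raise ValueError("L_inf, K and sigma must be positive")
        self.theta = {
            l: np.atleast_1d(np.asarray(v, dtype=float)) for l, v in self.theta.items()
        }

    def theta_dot(self, stage: int, x: np.ndarray | None) -> float:
        if x is None:
            return 0.0
        th = self.theta.get(stage)
        if th is None or th.size == 0:
            return 0.0
        return float(np.dot(th, np.asarray(x, dtype=float)))


def juvenile_expected_length(
    params: GrowthParams, x: np.ndarray | None = None
) -> float:
    """Expected age 0+ length: baseline VB length times exp(theta_1 . x)."""
    base = params.linf * (1.0 - np.exp(-params.k * (1.0 - params.t0)))
    return float(base * np.exp(params.theta_dot(1, x)))


def update_expected_length(
    params: GrowthParams,
    mu_prev: float,
    a: int,
    x: np.ndarray | None = None,
    literal_form: bool = False,
) -> float:
    """Expected length of age-class ``a`` from the previous class's length.

    Implements the Fabens increment form; ``literal_form=True`` returns
    the non-incremented variant (the increment alone).
    """
    if a not in range(2, N_AGES + 1):
        raise ValueError("a must be an age-class in 2..6")
    if mu_prev <= 0:
        raise ValueError("mu_prev must be positive")
    l = AGE_TO_STAGE[a]
    inc = (
        (params.linf - mu_prev)
        * (1.0 - np.exp(-params.k * (a - params.t0)))
        * np.exp(params.theta_dot(l, x))
    )
    return float(inc if literal_form else mu_prev + inc)


def baseline_lengths(params: GrowthParams, literal_form: bool = False) -> np.ndarray:
    """Deterministic VB chain (all covariates at their means), ages 1..6."""
    mu = np.empty(N_AGES)
    mu[0] = juvenile_expected_length(params)
    for a in range(2, N_AGES + 1):
        mu[a - 1] = update_expected_length(params, mu[a - 2], a, literal_form=literal_form)
    return mu


@dataclass(frozen=True)
class GrowthPriors:
    """Priors on growth parameters, in JAGS-style mean/precision notation.

    The second argument of each Normal is a precision and the
    Gamma(0.01, 0.01) on the observation error is a prior on the Normal
    precision tau.  Precision 0.001 (sd ~31.6) is weakly informative for
    parameters whose magnitude is small on that scale (t0 in years, the
    standardised-covariate coefficients), and those keep it.  For the
    millimetre-scale location parameters (L_inf ~ 350 mm, first-year
    expected lengths 200--330 mm) a zero-centred sd-31.6 Normal is strongly
    informative and shrinks them by tens of mm, which measurably biases K
    and t0 in simulation recovery; their default precision is therefore
    1e-6 (sd 1000 mm), the conventional vague setting.
    :meth:`notation_literal` gives the uniform precision-0.001 reading for
    comparison.
    """

    linf_prec: float = 1e-6
    t0_prec: float = 0.001
    k_shape: float = 1.0
    k_rate: float = 1.0
    eps_shape: float = 0.01
    eps_rate: float = 0.01
    beta_prec: float = 0.001
    mu_init_prec: float = 1e-6

    @classmethod
    def notation_literal(cls) -> "GrowthPriors":
        """Uniform precision-0.001 reading of every Normal prior."""
        return cls(linf_prec=0.001, mu_init_prec=0.001)

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.linf_prec,
                self.t0_prec,
                self.k_shape,
                self.k_rate,
                self.eps_shape,
                self.eps_rate,
                self.beta_prec,
                self.mu_init_prec,
            ]
        )


@dataclass
class _Prepared:
    X: np.ndarray  # (Y, S, 3, Mmax)
    M: np.ndarray  # (3,)
    stage_vars: dict[int, list[str]]
    n: np.ndarray  # (Y, S, 6) record counts
    s1: np.ndarray
    s2: np.ndarray
    rec_y: np.ndarray
    rec_s: np.ndarray
    rec_a: np.ndarray
    rec_len: np.ndarray
    years: np.ndarray
    sites: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.rec_len)


def _prepare(
    data: pd.DataFrame,
    table: CovariateTable,
    stage_vars: dict[int, list[str]] | None,
    exclude_recaptures: bool = False,
) -> _Prepared:
    X, M, stage_vars = table.design_arrays(stage_vars)
    years, sites = table.years, table.sites
    yidx = {y: i for i, y in enumerate(years)}
    sidx = {s: i for i, s in enumerate(sites)}
    df = data
    if exclude_recaptures and "recapture" in df.columns:
        df = df.loc[~df["recapture"].astype(bool)]
    ages = df["age_class"].to_numpy()
    if ages.min() < 1 or ages.max() > N_AGES:
        raise ValueError("age_class must be in 1..6 (ages 0+..5+)")
    if (df["fork_length_mm"] <= 0).any():
        raise ValueError("fork lengths must be positive")
    bad = set(zip(df["year"], df["site"])) - set(
        (y, s) for y in years for s in sites
    )
    if bad:
        raise ValueError(f"records outside the covariate frame: {sorted(bad)[:5]}")
    rec_y = df["year"].map(yidx).to_numpy(dtype=np.int64)
    rec_s = df["site"].map(sidx).to_numpy(dtype=np.int64)
    rec_a = ages.astype(np.int64) - 1
    rec_len = df["fork_length_mm"].to_numpy(dtype=float)
    shape = (len(years), len(sites), N_AGES)
    n = np.zeros(shape)
    s1 = np.zeros(shape)
    s2 = np.zeros(shape)
    np.add.at(n, (rec_y, rec_s, rec_a), 1.0)
    np.add.at(s1, (rec_y, rec_s, rec_a), rec_len)
    np.add.at(s2, (rec_y, rec_s, rec_a), rec_len**2)
    return _Prepared(X, M, stage_vars, n, s1, s2, rec_y, rec_s, rec_a, rec_len, years, sites)


def _params_to_vector(params: GrowthParams, prep: _Prepared) -> np.ndarray:
    theta = np.concatenate(
        [np.asarray(params.theta.get(l, np.zeros(prep.M[l - 1])), dtype=float) for l in (1, 2, 3)]
    ) if prep.M.sum() else np.empty(0)
    if theta.size != prep.M.sum():
        raise ValueError("theta lengths do not match the stage variable sets")
    if params.mu_init is None:
        raise ValueError("mu_init required to evaluate the likelihood")
    mu_init = np.asarray(params.mu_init, dtype=float)
    return np.concatenate(
        [
            [params.linf, np.log(params.k), params.t0, -2.0 * np.log(params.sigma)],
            theta,
            mu_init.ravel(),
        ]
    )


def growth_loglik(
    params: GrowthParams,
    data: pd.DataFrame,
    table: CovariateTable,
    stage_vars: dict[int, list[str]] | None = None,
    literal_form: bool = False,
) -> tuple[float, np.ndarray]:
    """Normal log-likelihood of individual lengths plus the pointwise vector."""
    prep = _prepare(data, table, stage_vars)
    x = _params_to_vector(params, prep)
    theta = x[4 : 4 + int(prep.M.sum())]
    mu_init = x[4 + int(prep.M.sum()) :].reshape(len(prep.sites), N_AGES - 1)
    mu = gk.compute_mu(
        params.linf, params.k, params.t0, theta, mu_init, prep.X, prep.M, literal_form
    )
    mu_rec = mu[prep.rec_y, prep.rec_s, prep.rec_a]
    pointwise = (
        -0.5 * np.log(2 * np.pi * params.sigma**2)
        - (prep.rec_len - mu_rec) ** 2 / (2 * params.sigma**2)
    )
    return float(pointwise.sum()), pointwise


def _heuristic_init(prep: _Prepared, rng: np.random.Generator) -> np.ndarray:
    """Data-informed start: coarse VB fit to pooled age means, jittered."""
    with np.errstate(invalid="ignore"):
        cell_mean = np.where(prep.n > 0, prep.s1 / np.maximum(prep.n, 1), np.nan)
    age_n = prep.n.sum(axis=(0, 1))
    age_mean = prep.s1.sum(axis=(0, 1)) / np.maximum(age_n, 1)
    present = age_n > 0
    best = (np.inf, 0.2, -1.5, float(np.nanmax(cell_mean)) * 1.05)
    ages = np.arange(1, N_AGES + 1, dtype=float)
    for K in np.linspace(0.05, 0.6, 18):
        for t0 in np.linspace(-4.0, 0.5, 18):
            gvec = 1.0 - np.exp(-K * (ages - t0))
            w = age_n[present]
            g, m = gvec[present], age_mean[present]
            linf = float(np.sum(w * g * m) / np.sum(w * g * g))
            sse = float(np.sum(w * (m - linf * g) ** 2))
            if linf > 0 and sse < best[0]:
                best = (sse, K, t0, linf)
    _, K0, t00, linf0 = best
    # pooled within-cell sd
    nz = prep.n > 1
    if nz.any():
        ss = prep.s2[nz] - prep.s1[nz] ** 2 / prep.n[nz]
        sigma0 = float(np.sqrt(max(ss.sum() / max((prep.n[nz] - 1).sum(), 1.0), 1.0)))
    else:
        sigma0 = 15.0
    gvec = 1.0 - np.exp(-K0 * (ages - t00))
    vb = linf0 * gvec
    mu_init0 = np.empty((len(prep.sites), N_AGES - 1))
    for si in range(len(prep.sites)):
        for a in range(2, N_AGES + 1):
            cm = cell_mean[0, si, a - 1]
            mu_init0[si, a - 2] = cm if np.isfinite(cm) else vb[a - 1]
    x0 = np.concatenate(
        [
            [
                linf0 * (1.0 + 0.03 * rng.standard_normal()),
                np.log(K0) + 0.1 * rng.standard_normal(),
                t00 + 0.2 * rng.standard_normal(),
                -2.0 * np.log(sigma0) + 0.2 * rng.standard_normal(),
            ],
            0.02 * rng.standard_normal(int(prep.M.sum())),
            (mu_init0 + 4.0 * rng.standard_normal(mu_init0.shape)).ravel(),
        ]
    )
    return x0


def _blocks(prep: _Prepared) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis blocks: (log K, t0) plus one per stage's theta.

    L_inf, the observation precision and the first-year expected lengths
    are not Metropolis blocks -- the sampler draws them by exact conjugate
    Gibbs.
    """
    starts, lens = [1], [2]
    off = 4
    for l in range(3):
        if prep.M[l] > 0:
            starts.append(off)
            lens.append(int(prep.M[l]))
        off += int(prep.M[l])
    return np.asarray(starts, dtype=np.int64), np.asarray(lens, dtype=np.int64)


def _param_names(prep: _Prepared) -> list[str]:
    names = ["Linf", "K", "t0", "sigma"]
    for l in (1, 2, 3):
        for v in prep.stage_vars.get(l, []):
            names.append(f"theta[{l},{v}]")
    for s in prep.sites:
        for a in range(2, N_AGES + 1):
            names.append(f"mu_init[s{s},a{a}]")
    return names


def theta_name(stage: int, variable: str) -> str:
    return f"theta[{stage},{variable}]"


def fit_growth(
    data: pd.DataFrame,
    table: CovariateTable,
    stage_vars: dict[int, list[str]] | None = None,
    priors: GrowthPriors | None = None,
    settings: McmcSettings | None = None,
    literal_form: bool = False,
    exclude_recaptures: bool = False,
    compute_pointwise: bool = True,
) -> PosteriorResult:
    """Fit the growth model by adaptive block Metropolis MCMC.

    Returns a :class:`PosteriorResult` whose draws are on the natural scale
    (Linf, K, t0, sigma, theta..., mu_init...) and whose
    ``pointwise_loglik`` matrix (pooled draws x observations) feeds LOO.
    Deterministic given ``settings.seed``; per-chain seeds are offsets of it.
    """
    priors = priors or GrowthPriors()
    settings = settings or McmcSettings(
        chains=3, iterations=30_000, burn_in=20_000, thin=100, seed=0
    )
    prep = _prepare(data, table, stage_vars, exclude_recaptures)
    starts, lens = _blocks(prep)
    pv = priors.to_vector()
    npar = 4 + int(prep.M.sum()) + len(prep.sites) * (N_AGES - 1)
    retained = settings.retained_per_chain
    draws_t = np.empty((settings.chains, retained, npar))
    for c in range(settings.chains):
        rng = np.random.default_rng(settings.seed + c)
        x0 = _heuristic_init(prep, rng)
        if not np.isfinite(gk.log_post(x0, prep.X, prep.M, prep.n, prep.s1, prep.s2, pv, literal_form)):
            raise RuntimeError("non-finite log-joint at the initial value")
        draws_t[c] = gk.sample_chain(
            x0,
            settings.iterations,
            settings.burn_in,
            settings.thin,
            (settings.seed + c) % (2**31 - 1),
            starts,
            lens,
            prep.X,
            prep.M,
            prep.n,
            prep.s1,
            prep.s2,
            pv,
            literal_form,
        )
    # back-transform to natural scale
    draws = draws_t.copy()
    draws[:, :, 1] = np.exp(draws_t[:, :, 1])  # K
    draws[:, :, 3] = np.exp(-0.5 * draws_t[:, :, 3])  # sigma = tau^-1/2
    pointwise = None
    if compute_pointwise:
        pooled = draws.reshape(-1, npar)
        pointwise = np.empty((pooled.shape[0], prep.n_obs))
        n_theta = int(prep.M.sum())
        for d in range(pooled.shape[0]):
            row = pooled[d]
            mu = gk.compute_mu(
                row[0],
                row[1],
                row[2],
                row[4 : 4 + n_theta],
                row[4 + n_theta :].reshape(len(prep.sites), N_AGES - 1),
                prep.X,
                prep.M,
                literal_form,
            )
            mu_rec = mu[prep.rec_y, prep.rec_s, prep.rec_a]
            sig = row[3]
            pointwise[d] = -0.5 * np.log(2 * np.pi * sig**2) - (
                prep.rec_len - mu_rec
            ) ** 2 / (2 * sig**2)
    result = PosteriorResult(draws, _param_names(prep), settings, pointwise_loglik=pointwise)
    result.prep = prep  # cached design for downstream summaries
    result.literal_form = literal_form
    return result


def map_fit(
    data: pd.DataFrame,
    table: CovariateTable,
    stage_vars: dict[int, list[str]] | None = None,
    priors: GrowthPriors | None = None,
    sigma_fixed: float | None = None,
    literal_form: bool = False,
) -> GrowthParams:
    """Maximum-a-posteriori point fit (quasi-Newton), mainly for checks."""
    priors = priors or GrowthPriors()
    prep = _prepare(data, table, stage_vars)
    pv = priors.to_vector()
    x0 = _heuristic_init(prep, np.random.default_rng(0))
    n_theta = int(prep.M.sum())
    if sigma_fixed is not None:
        x0[3] = -2.0 * np.log(sigma_fixed)

    def neg(x: np.ndarray) -> float:
        xx = x.copy()
        if sigma_fixed is not None:
            xx[3] = -2.0 * np.log(sigma_fixed)
        return -gk.log_post(xx, prep.X, prep.M, prep.n, prep.s1, prep.s2, pv, literal_form)

    # alternate simplex and quasi-Newton polish: the (L_inf, K, t0) ridge is
    # nearly flat, so a single pass stalls short of the optimum
    res = minimize(neg, x0, method="Nelder-Mead", options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
    for _ in range(3):
        res = minimize(neg, res.x, method="L-BFGS-B", options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12})
        res = minimize(neg, res.x, method="Nelder-Mead", options={"maxiter": 10000, "xatol": 1e-10, "fatol": 1e-12})
    x = res.x
    return GrowthParams(
        linf=float(x[0]),
        k=float(np.exp(x[1])),
        t0=float(x[2]),
        sigma=float(np.exp(-0.5 * x[3])) if sigma_fixed is None else sigma_fixed,
        theta={
            l: x[4 + int(prep.M[:l - 1].sum()) : 4 + int(prep.M[:l].sum())]
            for l in (1, 2, 3)
        },
        mu_init=x[4 + n_theta :].reshape(len(prep.sites), N_AGES - 1),
    )


def _per_draw_mu(post: PosteriorResult) -> np.ndarray:
    prep = post.prep
    pooled = post.pooled()
    n_theta = int(prep.M.sum())
    out = np.empty((pooled.shape[0], prep.X.shape[0], prep.X.shape[1], N_AGES))
    for d in range(pooled.shape[0]):
        row = pooled[d]
        out[d] = gk.compute_mu(
            row[0],
            row[1],
            row[2],
            row[4 : 4 + n_theta],
            row[4 + n_theta :].reshape(len(prep.sites), N_AGES - 1),
            prep.X,
            prep.M,
            getattr(post, "literal_form", False),
        )
    return out


def expected_length_series(
    post: PosteriorResult,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site-averaged expected length at age per year, plus a year trend.

    Returns ``(series, trend)``: ``series`` has per (year, age_class) the
    posterior mean and 95% CrI of the site-averaged expected length;
    ``trend`` holds, per age-class, the OLS year slope fitted post hoc to
    each draw's annual series (mean slope and 95% CrI).
    """
    prep = post.prep
    mu = _per_draw_mu(post).mean(axis=2)  # (draws, Y, A)
    years = prep.years.astype(float)
    rows = []
    for yi, y in enumerate(prep.years):
        for a in range(1, N_AGES + 1):
            v = mu[:, yi, a - 1]
            lo, hi = np.quantile(v, [0.025, 0.975])
            rows.append((int(y), a, float(v.mean()), float(lo), float(hi)))
    series = pd.DataFrame(rows, columns=["year", "age_class", "mean", "lo95", "hi95"])
    yc = years - years.mean()
    denom = float(np.sum(yc**2))
    trend_rows = []
    for a in range(1, N_AGES + 1):
        slopes = mu[:, :, a - 1] @ yc / denom
        lo, hi = np.quantile(slopes, [0.025, 0.975])
        trend_rows.append((a, float(slopes.mean()), float(lo), float(hi)))
    trend = pd.DataFrame(
        trend_rows, columns=["age_class", "slope_mm_per_year", "lo95", "hi95"]
    )
    return series, trend


#: representative age-class shown for each stage's marginal effect
STAGE_REPRESENTATIVE_AGE = {1: 1, 2: 2, 3: 3}


def marginal_effect(
    post: PosteriorResult,
    table: CovariateTable,
    variable: str,
    stage: int,
    grid: np.ndarray,
    age: int | None = None,
) -> pd.DataFrame:
    """Marginal effect of one retained covariate on expected length.

    Evaluates expected length across ``grid`` (raw covariate units,
    converted through the stored standardisation scale) holding all other
    covariates at their means and, for ages >= 2, the previous age-class's
    expected length fixed at its posterior-mean baseline.
    """
    prep = post.prep
    if variable not in prep.stage_vars.get(stage, []):
        raise ValueError(f"variable {variable!r} not retained for stage {stage}")
    if variable not in table.scales:
        raise ValueError(f"no standardisation scale stored for {variable!r}")
    mean, sd = table.scales[variable]
    g = (np.asarray(grid, dtype=float) - mean) / sd
    age = age if age is not None else STAGE_REPRESENTATIVE_AGE[stage]
    name = theta_name(stage, variable)
    th = post.param(name)
    linf = post.param("Linf")
    kk = post.param("K")
    tt0 = post.param("t0")
    # posterior-mean baseline of the previous age-class
    pm = GrowthParams(
        linf=float(linf.mean()), k=float(kk.mean()), t0=float(tt0.mean()), sigma=1.0
    )
    base = baseline_lengths(pm)
    curves = np.empty((len(th), len(g)))
    if age == 1:
        for d in range(len(th)):
            curves[d] = (
                linf[d] * (1 - np.exp(-kk[d] * (1 - tt0[d]))) * np.exp(th[d] * g)
            )
    else:
        mu_prev = base[age - 2]
        for d in range(len(th)):
            inc = (linf[d] - mu_prev) * (1 - np.exp(-kk[d] * (age - tt0[d])))
            curves[d] = mu_prev + inc * np.exp(th[d] * g)
    lo, hi = np.quantile(curves, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "raw_value": np.asarray(grid, dtype=float),
            "std_value": g,
            "mean": curves.mean(axis=0),
            "lo95": lo,
            "hi95": hi,
        }
    )
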