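"""Bayesian N-mixture model for k-pass depletion electrofishing.

Each survey unit (year x site x age/size-class) has a latent integer
abundance ``N ~ Poisson(lambda)`` with ``log(lambda) = alpha`` and
``alpha ~ Normal(0, sd 10)``.  The observation model is the sequential
depletion series

    C_1 ~ Binomial(p_g, N)
    C_2 ~ Binomial(p_g, N - C_1)
    C_3 ~ Binomial(p_g, N - C_1 - C_2)

with a per-group capture probability ``p_g ~ Beta(1, 1)`` shared across
units (grayling: g=1 for age 0+, g=2 for ages 1+..5+; trout: one group).
Single-pass units (k=1) enter the same joint model and share p with
multi-pass units.

Inference is Metropolis-within-Gibbs with two exact conditional updates:

* ``p_g | N, C ~ Beta(1 + total catch, 1 + total escapes)`` where escapes
  sum ``N - cum_catch_j`` over passes;
* ``N | alpha, p, C = total catch + Poisson(lambda * (1-p)^k)`` -- under a
  Poisson prior the never-caught remainder is itself Poisson-thinned;

and an adaptive random-walk Metropolis step for each ``alpha | N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mcmc import McmcSettings, gelman_rubin, summarise

__all__ = [
    "DepletionData",
    "AbundanceEstimate",
    "nmixture_logjoint",
    "fit_abundance",
    "abundance_covariates",
    "GRAYLING_GROUPS",
]

ALPHA_SD = 10.0  # prior sd of log mean abundance (variance 100)

#: Capture-probability groups for grayling age-classes 1..6 (0+..5+).
GRAYLING_GROUPS: dict[int, int] = {1: 1, 2: 2, 3: 2, 4: 2, 5: 2, 6: 2}


@dataclass
class DepletionData:
    """Per-unit depletion catches, validated and grouped.

    ``catches`` is a DataFrame (year, site, cls, pass_idx ('pass' in CSV),
    count); ``groups`` maps class id -> capture-probability group g.
    """

    units: pd.DataFrame  # one row per (year, site, cls): total, k, g
    catch_matrix: np.ndarray  # (n_units, k_max), -1 padding
    cum_matrix: np.ndarray  # cumulative catches, same shape

    @classmethod
    def from_frame(cls, catches: pd.DataFrame, groups: dict[int, int]) -> "DepletionData":
        df = catches.copy()
        if "pass" in df.columns and "pass_idx" not in df.columns:
            df = df.rename(columns={"pass": "pass_idx"})
        counts = df["count"].to_numpy()
        if not np.all(counts == np.floor(counts)) or (counts < 0).any():
            raise ValueError("catch counts must be non-negative integers")
        df["count"] = df["count"].astype(np.int64)
        keys = ["year", "site", "cls"]
        units = []
        rows = []
        for (y, s, a), grp in df.groupby(keys, sort=True):
            passes = grp.sort_values("pass_idx")
            pidx = passes["pass_idx"].to_numpy()
            if not np.array_equal(pidx, np.arange(1, len(pidx) + 1)):
                raise ValueError(
                    f"unit (year={y}, site={s}, class={a}): pass indices must be "
                    f"contiguous from 1, got {pidx.tolist()}"
                )
            if a not in groups:
                raise ValueError(f"class {a} has no capture-probability group")
            c = passes["count"].to_numpy()
            units.append(
                {"year": y, "site": s, "cls": a, "total": int(c.sum()), "k": len(c), "g": groups[a]}
            )
            rows.append(c)
        kmax = max(len(r) for r in rows)
        cm = -np.ones((len(rows), kmax), dtype=np.int64)
        for i, r in enumerate(rows):
            cm[i, : len(r)] = r
        cum = np.where(cm >= 0, np.cumsum(np.where(cm >= 0, cm, 0), axis=1), -1)
        return cls(pd.DataFrame(units), cm, cum)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_groups(self) -> int:
        return int(self.units["g"].max())


def _depletion_loglik_unit(c: np.ndarray, N: int, p: float) -> float:
    """Log-probability of one unit's sequential catches given N and p."""
    lp = 0.0
    remaining = N
    for cj in c:
        if remaining < cj:
            return -np.inf
        lp += stats.binom.logpmf(cj, remaining, p)
        remaining -= cj
    return float(lp)


def nmixture_logjoint(
    N: np.ndarray,
    alpha: np.ndarray,
    p: np.ndarray,
    data: DepletionData,
) -> float:
    """Log joint density of the depletion N-mixture model.

    Sums the Poisson(N | exp(alpha)) prior, the sequential binomial catch
    terms, the Normal(0, sd 10) prior on each alpha, and the Beta(1, 1)
    prior on each p (constant).  Returns ``-inf`` whenever a remaining pool
    would go negative or N < total catch.
    """
    N = np.asarray(N)
    if not np.issubdtype(N.dtype, np.integer):
        if not np.all(N == np.floor(N)):
            raise ValueError("N must be integer-valued")
        N = N.astype(np.int64)
    lam = np.exp(np.asarray(alpha, dtype=float))
    lp = float(np.sum(stats.poisson.logpmf(N, lam)))
    lp += float(np.sum(stats.norm.logpdf(alpha, 0.0, ALPHA_SD)))
    g = data.units["g"].to_numpy()
    for i in range(data.n_units):
        c = data.catch_matrix[i]
        c = c[c >= 0]
        lp += _depletion_loglik_unit(c, int(N[i]), float(p[g[i] - 1]))
        if not np.isfinite(lp):
            return -np.inf
    return lp


@dataclass
class AbundanceEstimate:
    """Posterior abundance summaries per unit plus capture probabilities."""

    table: pd.DataFrame  # year, site, cls, mean, lo95, hi95, rhat
    p_summary: pd.DataFrame  # group, mean, lo95, hi95, rhat
    converged: bool
    settings: McmcSettings
    n_draws: np.ndarray  # pooled posterior draws of N, (draws, units)
    p_draws: np.ndarray  # pooled draws of p, (draws, groups)
    units: pd.DataFrame


def fit_abundance(
    catches: pd.DataFrame,
    groups: dict[int, int] | None = None,
    settings: McmcSettings | None = None,
    p_fixed: float | None = None,
) -> AbundanceEstimate:
    """Fit the depletion N-mixture model by Metropolis-within-Gibbs.

    Parameters
    ----------
    catches : DataFrame (year, site, cls, pass_idx, count).
    groups : class -> capture group map (default: grayling grouping).
    settings : chains/iterations/burn-in/thin/seed
        (default 3 x 30,000, burn-in 10,000, thin 100).
    p_fixed : clamp all capture probabilities (used for degenerate-prior
        checks); skips the Beta update.

    The latent N update is exact: given alpha and p the uncaught remainder
    is Poisson(lambda (1-p)^k), which implicitly truncates N at the
    observed total and explores the full upper tail (equivalent to a
    truncation bound far above total + 10*lambda).
    """
    groups = groups if groups is not None else GRAYLING_GROUPS
    settings = settings or McmcSettings(
        chains=3, iterations=30_000, burn_in=10_000, thin=100, seed=0
    )
    data = DepletionData.from_frame(catches, groups)
    n_units, n_groups = data.n_units, data.n_groups
    g = data.units["g"].to_numpy()
    k = data.units["k"].to_numpy()
    total = data.units["total"].to_numpy()
    # per-unit sum over passes of cumulative catch (for the escape count)
    cum = np.where(data.cum_matrix >= 0, data.cum_matrix, 0)
    sum_cum = cum.sum(axis=1)
    n_pass = k  # escapes per pass j: N - cum_j  ->  sum_j = k*N - sum_cum

    retained = settings.retained_per_chain
    N_draws = np.empty((settings.chains, retained, n_units), dtype=np.int64)
    a_draws = np.empty((settings.chains, retained, n_units))
    p_draws = np.empty((settings.chains, retained, n_groups))

    for c in range(settings.chains):
        rng = np.random.default_rng(settings.seed + c)
        N = total + rng.poisson(np.maximum(total, 1) * 0.3 + 1)
        alpha = np.log(np.maximum(N, 1).astype(float)) + 0.1 * rng.standard_normal(n_units)
        p = np.full(n_groups, 0.5) if p_fixed is None else np.full(n_groups, p_fixed)
        step = np.full(n_units, 0.5)
        ki = 0
        for it in range(settings.iterations):
            lam = np.exp(alpha)
            # --- N | alpha, p : total + Poisson(lambda * (1-p)^k) ---
            q = (1.0 - p[g - 1]) ** k
            N = total + rng.poisson(lam * q)
            # --- p_g | N, C : Beta(1 + catches, 1 + escapes) ---
            if p_fixed is None:
                escapes = n_pass * N - sum_cum
                for gi in range(n_groups):
                    m = g == gi + 1
                    p[gi] = rng.beta(1 + total[m].sum(), 1 + escapes[m].sum())
            # --- alpha | N : random-walk Metropolis, vectorised ---
            prop = alpha + step * rng.standard_normal(n_units)
            def _lp(a: np.ndarray) -> np.ndarray:
                return N * a - np.exp(a) - a**2 / (2 * ALPHA_SD**2)
            log_acc = _lp(prop) - _lp(alpha)
            acc = np.log(rng.uniform(size=n_units)) < log_acc
            alpha = np.where(acc, prop, alpha)
            if it < settings.burn_in:
                gamma = min(0.25, 5.0 / np.sqrt(it + 10.0))
                step *= np.exp(gamma * (acc.astype(float) - 0.44))
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                if ki < retained:
                    N_draws[c, ki] = N
                    a_draws[c, ki] = alpha
                    p_draws[c, ki] = p
                    ki += 1

    # R-hat on alpha (continuous) stands in for each unit's N; p has its own.
    rhat_alpha = gelman_rubin(a_draws)
    rhat_p = (
        gelman_rubin(p_draws) if p_fixed is None else np.full(n_groups, np.nan)
    )
    pooled_N = N_draws.reshape(-1, n_units)
    pooled_p = p_draws.reshape(-1, n_groups)
    summ = summarise(pooled_N.astype(float))
    table = data.units[["year", "site", "cls"]].copy()
    table[["mean", "sd", "lo95", "hi95"]] = summ[["mean", "sd", "lo95", "hi95"]].to_numpy()
    table["rhat"] = rhat_alpha
    psumm = summarise(pooled_p)
    psumm.insert(0, "group", np.arange(1, n_groups + 1))
    psumm["rhat"] = rhat_p
    finite_rhat = np.concatenate([rhat_alpha, rhat_p[np.isfinite(rhat_p)]])
    converged = bool(np.all(finite_rhat < 1.1))
    return AbundanceEstimate(
        table=table,
        p_summary=psumm.reset_index(drop=True),
        converged=converged,
        settings=settings,
        n_draws=pooled_N,
        p_draws=pooled_p,
        units=data.units,
    )


#: stage -> grayling age-classes whose posterior-mean N is summed
STAGE_CLASS_SUMS: dict[int, list[int]] = {1: [1], 2: [2], 3: [3, 4, 5, 6]}

STAGE_VARIABLE_NAMES: dict[int, str] = {
    1: "grayling_juv_abund",
    2: "grayling_subadult_abund",
    3: "grayling_adult_abund",
}


def abundance_covariates(
    est: AbundanceEstimate,
    stage_sums: dict[int, list[int]] | None = None,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Posterior-mean abundances as year x site covariates.

    For grayling: stage 1 = class 1 (age 0+), stage 2 = class 2 (age 1+),
    stage 3 = sum of classes 3..6 (ages 2+..5+).  For trout call with
    ``stage_sums={1: [small_cls], 2: [large_cls]}`` and matching names.
    Returns long format (year, site, variable, value).
    """
    stage_sums = stage_sums if stage_sums is not None else STAGE_CLASS_SUMS
    names = names if names is not None else STAGE_VARIABLE_NAMES
    tab = est.table
    years = np.sort(tab["year"].unique())
    sites = np.sort(tab["site"].unique())
    rows = []
    for stage, classes in stage_sums.items():
        sub = tab.loc[tab["cls"].isin(classes)]
        agg = sub.groupby(["year", "site"])["mean"].agg(["sum", "size"])
        for y in years:
            for s in sites:
                if (y, s) not in agg.index or agg.loc[(y, s), "size"] != len(classes):
                    raise ValueError(
                        f"missing abundance estimate for year={y}, site={s}, "
                        f"classes {classes}"
                    )
                rows.append((y, s, names[stage], float(agg.loc[(y, s), "sum"])))
    return pd.DataFrame(rows, columns=["year", "site", "variable", "value"])
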