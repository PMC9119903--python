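"""Shared posterior-sampling contract and convergence diagnostics.

Every stochastic fit in this package runs three (by default) independent
Markov chains from a single integer seed, retains post-burn-in thinned draws,
and reports the classic Gelman--Rubin potential scale reduction factor per
parameter.  The sampler here is an adaptive block random-walk Metropolis:
proposal covariances per block are learned during burn-in (Haario-style
empirical covariance with a Robbins--Monro global scale targeting ~23%
acceptance) and frozen afterwards, so the retained draws come from a fixed
Markov kernel.

Model-specific samplers (the depletion Gibbs sampler in
:mod:`graylinggrowth.abundance`, the compiled growth sampler in
:mod:`graylinggrowth.growth`) honour the same contract -- seed determinism,
burn-in/thinning arithmetic, R-hat -- and reuse the summaries implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "McmcSettings",
    "PosteriorResult",
    "run_mcmc",
    "gelman_rubin",
    "summarise",
]

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class McmcSettings:
    """MCMC run configuration.

    Parameters
    ----------
    chains : number of independent chains (>= 2 for R-hat).
    iterations : total iterations per chain, including burn-in.
    burn_in : iterations discarded from the start of each chain.
    thin : keep every ``thin``-th post-burn-in iteration.
    seed : master seed; chain ``c`` uses ``seed + c`` offsets internally.
    """

    chains: int = 3
    iterations: int = 30_000
    burn_in: int = 20_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.seed is None:
            raise ValueError("seed is mandatory for any stochastic run")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorResult:
    """Multi-chain posterior draws plus per-parameter summaries.

    Attributes
    ----------
    draws : array, shape (chains, retained, n_params)
    param_names : parameter labels, length n_params
    summary : DataFrame indexed by parameter with columns
        mean, sd, lo95, hi95, rhat
    settings : the settings the run used
    pointwise_loglik : optional (chains*retained, n_obs) matrix for LOO
    converged : True when every R-hat < 1.1
    """

    draws: np.ndarray
    param_names: list[str]
    settings: McmcSettings
    pointwise_loglik: np.ndarray | None = None
    summary: pd.DataFrame = field(init=False)
    converged: bool = field(init=False)

    def __post_init__(self) -> None:
        rhat = gelman_rubin(self.draws)
        summ = summarise(self.pooled())
        summ["rhat"] = rhat
        summ.index = pd.Index(self.param_names, name="parameter")
        self.summary = summ
        self.converged = bool(np.all(rhat < RHAT_THRESHOLD))

    def pooled(self) -> np.ndarray:
        """Draws pooled across chains, shape (chains*retained, n_params)."""
        c, n, p = self.draws.shape
        return self.draws.reshape(c * n, p)

    def param(self, name: str) -> np.ndarray:
        return self.pooled()[:, self.param_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (chain, iter, parameter, value)."""
        c, n, _ = self.draws.shape
        recs = []
        for ci in range(c):
            for pi, pname in enumerate(self.param_names):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": ci,
                            "iter": np.arange(n),
                            "parameter": pname,
                            "value": self.draws[ci, :, pi],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)


def gelman_rubin(draws: np.ndarray, split: bool = False) -> np.ndarray:
    """Classic Gelman--Rubin potential scale reduction factor per parameter.

    Uses the original (non-split) formulation
    ``Rhat = sqrt((n-1)/n + B/(n*W))`` with ``B`` the between-chain variance
    of chain means (times n) and ``W`` the mean within-chain variance.  With
    ``split=True`` each chain is halved first (the modern split-R-hat).

    Parameters
    ----------
    draws : array (chains, n, params)

    Raises
    ------
    ValueError
        for fewer than 2 chains, fewer than 10 draws, or a degenerate
        parameter whose within-chain variance is zero in every chain.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    if split:
        c, n, p = draws.shape
        half = n // 2
        draws = np.concatenate([draws[:, :half], draws[:, n - half :]], axis=0)
    c, n, p = draws.shape
    if c < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if n < 2:
        raise ValueError("R-hat needs at least 2 retained draws per chain")
    chain_means = draws.mean(axis=1)  # (c, p)
    chain_vars = draws.var(axis=1, ddof=1)  # (c, p)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    if np.any(W <= 0):
        bad = np.nonzero(W <= 0)[0]
        raise ValueError(
            f"degenerate draws: zero within-chain variance for parameter index {bad.tolist()}"
        )
    return np.sqrt((n - 1) / n + B / (n * W))


def summarise(pooled: np.ndarray) -> pd.DataFrame:
    """Posterior mean, sd and equal-tailed 95% credible interval.

    Quantiles use linear interpolation between order statistics, the same
    convention as the covariate module's flow quantiles.
    """
    pooled = np.asarray(pooled, dtype=float)
    if pooled.ndim == 1:
        pooled = pooled[:, None]
    lo, hi = np.quantile(pooled, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "lo95": lo,
            "hi95": hi,
        }
    )


class MetropolisModel:
    """Target for :func:`run_mcmc`.

    Parameters
    ----------
    log_joint : maps a parameter vector to the (unnormalised) log posterior.
    n_params : dimensionality.
    init : optional callable ``(rng) -> x0``; when None, ``prior_draw`` is
        required.  Models supply a data-informed, per-chain-jittered
        initialiser when vague priors would start chains unreasonably far
        from the posterior.
    prior_draw : optional callable ``(rng) -> x0`` drawing from the prior.
    blocks : optional list of index arrays updated jointly; default one
        block per parameter.
    """

    def __init__(
        self,
        log_joint: Callable[[np.ndarray], float],
        n_params: int,
        param_names: Sequence[str] | None = None,
        init: Callable[[np.random.Generator], np.ndarray] | None = None,
        prior_draw: Callable[[np.random.Generator], np.ndarray] | None = None,
        blocks: Sequence[np.ndarray] | None = None,
    ) -> None:
        self.log_joint = log_joint
        self.n_params = n_params
        self.param_names = (
            list(param_names) if param_names is not None else [f"p{i}" for i in range(n_params)]
        )
        if init is None and prior_draw is None:
            raise ValueError("either init or prior_draw must be supplied")
        self._init = init if init is not None else prior_draw
        if blocks is None:
            blocks = [np.array([i]) for i in range(n_params)]
        self.blocks = [np.asarray(b, dtype=np.intp) for b in blocks]

    def initial_value(self, rng: np.random.Generator, retries: int = 50) -> np.ndarray:
        for _ in range(retries):
            x0 = np.asarray(self._init(rng), dtype=float)
            if np.isfinite(self.log_joint(x0)):
                return x0
        raise RuntimeError("could not find a starting point with finite log-joint")


def run_mcmc(model: MetropolisModel, settings: McmcSettings) -> PosteriorResult:
    """Adaptive block random-walk Metropolis.

    Reproducible given ``settings.seed``: chain ``c`` uses an independent
    ``numpy`` Generator seeded at ``seed + c``.  Adaptation (block proposal
    covariance + global scale) happens only during burn-in.
    """
    all_draws = np.empty(
        (settings.chains, settings.retained_per_chain, model.n_params), dtype=float
    )
    for c in range(settings.chains):
        rng = np.random.default_rng(settings.seed + c)
        all_draws[c] = _one_chain(model, settings, rng)
    return PosteriorResult(all_draws, model.param_names, settings)


def _one_chain(
    model: MetropolisModel, settings: McmcSettings, rng: np.random.Generator
) -> np.ndarray:
    x = model.initial_value(rng)
    lp = model.log_joint(x)
    nb = len(model.blocks)
    # per-block adaptive state
    log_scale = np.zeros(nb)
    means = [x[b].copy() for b in model.blocks]
    covs = [np.eye(len(b)) * 0.1 for b in model.blocks]
    counts = np.zeros(nb)
    chols = [np.linalg.cholesky(c + 1e-9 * np.eye(len(c))) for c in covs]

    kept = np.empty((settings.retained_per_chain, model.n_params))
    ki = 0
    for it in range(settings.iterations):
        adapting = it < settings.burn_in
        for bi, b in enumerate(model.blocks):
            d = len(b)
            step = np.exp(log_scale[bi]) * 2.38 / np.sqrt(d)
            prop = x.copy()
            prop[b] = x[b] + step * (chols[bi] @ rng.standard_normal(d))
            lp_prop = model.log_joint(prop)
            accept = np.log(rng.uniform()) < lp_prop - lp
            if accept:
                x, lp = prop, lp_prop
            if adapting:
                gamma = min(0.25, 5.0 / np.sqrt(it + 10.0))
                log_scale[bi] += gamma * ((1.0 if accept else 0.0) - 0.234)
                counts[bi] += 1
                w = 1.0 / (counts[bi] + 5.0)
                delta = x[b] - means[bi]
                means[bi] += w * delta
                covs[bi] = (1 - w) * covs[bi] + w * np.outer(delta, delta)
                if counts[bi] % 50 == 0:
                    chols[bi] = np.linalg.cholesky(covs[bi] + 1e-9 * np.eye(d))
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            if ki < kept.shape[0]:
                kept[ki] = x
                ki += 1
    return kept
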