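"""Staged covariate simplification and LOO-based model comparison.

The simplification procedure mirrors a stage-wise build-up: fit a saturated
juvenile model (sub-adult and adult covariates omitted), iteratively remove
the juvenile coefficient whose 95% credible interval most centrally
straddles zero, then extend to a saturated sub-adult model keeping the
retained juvenile variables, and repeat for the adult stage.  The final
simplified adult model is the "full model"; it is verified against
"candidate full models" that re-add the last variable removed for each
stage, compared by PSIS-LOO (Pareto-smoothed importance-sampling
leave-one-out cross-validation), selecting the most parsimonious model with
the lowest LOOIC.

PSIS is implemented from its published algorithm: per-observation importance
ratios, generalised-Pareto smoothing of the largest ~20% of ratios (profile
posterior-mean fit of the GPD shape), truncation at the raw maximum, and
the Pareto-k shape diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .growth import theta_name
from .mcmc import PosteriorResult

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "LooResult",
    "SimplificationError",
    "simplify_stage",
    "staged_simplification",
    "candidate_full_models",
    "psis_loo",
    "select_model",
]


@dataclass
class ModelSpec:
    """Per-stage retained covariate sets plus the removal lineage."""

    stage_vars: dict[int, list[str]]
    lineage: dict[int, list[str]] = field(default_factory=lambda: {1: [], 2: [], 3: []})
    notes: list[str] = field(default_factory=list)

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            {l: list(v) for l, v in self.stage_vars.items()},
            {l: list(v) for l, v in self.lineage.items()},
            list(self.notes),
        )

    def n_coefficients(self) -> int:
        return sum(len(v) for v in self.stage_vars.values())

    def to_dict(self) -> dict:
        return {
            "stage_vars": {str(l): v for l, v in self.stage_vars.items()},
            "lineage": {str(l): v for l, v in self.lineage.items()},
            "notes": self.notes,
        }


class SimplificationError(RuntimeError):
    """Raised when a simplification fit fails to converge (abort mode)."""

    def __init__(self, message: str, spec: ModelSpec):
        super().__init__(message)
        self.spec = spec


FitFn = Callable[[ModelSpec, int], PosteriorResult]


def _derive_seed(master_seed: int, position: int) -> int:
    return int((master_seed + 7919 * (position + 1)) % (2**31 - 1))


def simplify_stage(
    spec: ModelSpec,
    stage: int,
    fit_fn: FitFn,
    master_seed: int = 0,
    seed_offset: int = 0,
    batch: bool = False,
    on_nonconvergence: str = "warn",
) -> tuple[ModelSpec, PosteriorResult | None]:
    """Iteratively remove zero-straddling coefficients from one stage.

    Repeats fit -> inspect until every retained coefficient's equal-tailed
    95% credible interval excludes zero (or the set empties).  By default
    one variable is removed per refit -- the one whose interval most
    centrally straddles zero, i.e. smallest |posterior mean| / sd; with
    ``batch=True`` all straddling variables go at once.

    ``on_nonconvergence`` controls what a fit with any R-hat >= 1.1 does:
    ``"warn"`` (default) records a note and continues, ``"abort"`` raises
    :class:`SimplificationError` carrying the lineage so far.

    Returns the updated spec and the final stage fit (None if the stage
    set was empty to begin with).
    """
    spec = spec.copy()
    if not spec.stage_vars.get(stage):
        return spec, None
    pos = seed_offset
    while True:
        post = fit_fn(spec, _derive_seed(master_seed, pos))
        pos += 1
        if not post.converged:
            msg = (
                f"fit during stage-{stage} simplification did not converge "
                f"(max R-hat {post.summary['rhat'].max():.3f})"
            )
            if on_nonconvergence == "abort":
                raise SimplificationError(msg, spec)
            log.warning(msg)
            spec.notes.append(msg)
        straddle = []
        for v in spec.stage_vars[stage]:
            row = post.summary.loc[theta_name(stage, v)]
            if row["lo95"] <= 0.0 <= row["hi95"]:
                z = abs(row["mean"]) / row["sd"] if row["sd"] > 0 else 0.0
                straddle.append((z, v))
        if not straddle:
            return spec, post
        straddle.sort()
        to_remove = [v for _, v in straddle] if batch else [straddle[0][1]]
        for v in to_remove:
            spec.stage_vars[stage].remove(v)
            spec.lineage[stage].append(v)
        if not spec.stage_vars[stage]:
            # refit once more so the returned posterior matches the spec
            post = fit_fn(spec, _derive_seed(master_seed, pos))
            return spec, post


def staged_simplification(
    saturated: ModelSpec,
    fit_fn: FitFn,
    master_seed: int = 0,
    batch: bool = False,
    on_nonconvergence: str = "warn",
) -> tuple[ModelSpec, PosteriorResult]:
    """Juvenile -> sub-adult -> adult staged simplification.

    While a stage is being simplified, later stages' covariates are omitted
    entirely (their coefficients fixed at zero by exclusion); earlier
    stages keep only their retained variables.  Returns the final spec
    ("full model") and its fit.
    """
    work = ModelSpec({1: [], 2: [], 3: []})
    post: PosteriorResult | None = None
    offset = 0
    for stage in (1, 2, 3):
        work.stage_vars[stage] = list(saturated.stage_vars.get(stage, []))
        work, post = simplify_stage(
            work,
            stage,
            fit_fn,
            master_seed=master_seed,
            seed_offset=offset,
            batch=batch,
            on_nonconvergence=on_nonconvergence,
        )
        offset += 1 + len(work.lineage[stage])
    if post is None:
        post = fit_fn(work, _derive_seed(master_seed, offset))
    return work, post


def candidate_full_models(full: ModelSpec) -> list[ModelSpec]:
    """One candidate per stage: the full model plus that stage's last removal."""
    candidates = []
    for stage in (1, 2, 3):
        lineage = full.lineage.get(stage, [])
        if not lineage:
            log.info("stage %d had no removals; candidate skipped", stage)
            continue
        cand = full.copy()
        cand.stage_vars[stage] = cand.stage_vars[stage] + [lineage[-1]]
        cand.notes.append(f"re-added {lineage[-1]!r} to stage {stage}")
        candidates.append(cand)
    return candidates


# ---------------------------------------------------------------------------
# PSIS-LOO


def _gpd_fit(x: np.ndarray) -> tuple[float, float]:
    """Generalised-Pareto (k, sigma) fit by the profile posterior-mean method.

    Zhang & Stephens (2009) estimator with the small-sample shape
    regularisation used by the PSIS algorithm.
    """
    x = np.sort(x)
    n = len(x)
    prior_bs, prior_k = 3.0, 10.0
    m = 30 + int(np.sqrt(n))
    bs = 1.0 - np.sqrt(m / (np.arange(1, m + 1) - 0.5))
    bs /= prior_bs * x[int(n / 4 + 0.5) - 1]
    bs += 1.0 / x[-1]
    ks = -bs[:, None] * x[None, :]
    ks = np.mean(np.log1p(ks), axis=1)
    L = n * (np.log(-bs / ks) - ks - 1.0)
    w = 1.0 / np.sum(np.exp(L[None, :] - L[:, None]), axis=1)
    b_post = float(np.sum(bs * w))
    k_post = float(np.mean(np.log1p(-b_post * x)))
    k_post = (n * k_post + prior_k * 0.5) / (n + prior_k)
    sigma = -k_post / b_post
    return k_post, sigma


def _psis_smooth(log_ratios: np.ndarray, tail_frac: float = 0.2) -> tuple[np.ndarray, float]:
    """Smooth one observation's log importance ratios; return (lw, khat)."""
    S = len(log_ratios)
    lw = log_ratios - log_ratios.max()
    M = int(np.ceil(min(tail_frac * S, 3.0 * np.sqrt(S))))
    if M < 5:
        return lw, -np.inf
    order = np.argsort(lw)
    tail_idx = order[S - M :]
    cutoff_lw = lw[order[S - M - 1]]
    cutoff = np.exp(cutoff_lw)
    exceed = np.exp(lw[tail_idx]) - cutoff
    if np.allclose(exceed, 0.0):
        return lw, -np.inf
    k, sigma = _gpd_fit(exceed)
    if np.isfinite(k) and sigma > 0:
        # expected order statistics of the fitted GPD replace the tail
        q = (np.arange(1, M + 1) - 0.5) / M
        if abs(k) < 1e-12:
            quant = -sigma * np.log1p(-q)
        else:
            quant = sigma / k * ((1.0 - q) ** (-k) - 1.0)
        smoothed = np.log(np.maximum(cutoff + quant, 1e-300))
        lw = lw.copy()
        lw[tail_idx] = np.minimum(smoothed, 0.0)  # truncate at raw max (=0)
    return lw, k


@dataclass
class LooResult:
    """PSIS-LOO estimate of expected log pointwise predictive density."""

    pointwise: np.ndarray  # elpd_i per observation
    pareto_k: np.ndarray
    warn: bool
    n_draws: int

    @property
    def elpd(self) -> float:
        return float(self.pointwise.sum())

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd

    @property
    def se(self) -> float:
        n = len(self.pointwise)
        return float(np.sqrt(n * np.var(self.pointwise, ddof=1)))

    @property
    def n_obs(self) -> int:
        return len(self.pointwise)

    def elpd_diff(self, other: "LooResult") -> tuple[float, float]:
        """elpd(self) - elpd(other) and the SE of the pointwise difference."""
        if self.n_obs != other.n_obs:
            raise ValueError("LOO results cover different observation sets")
        d = self.pointwise - other.pointwise
        return float(d.sum()), float(np.sqrt(len(d) * np.var(d, ddof=1)))


def psis_loo(loglik: np.ndarray, tail_frac: float = 0.2) -> LooResult:
    """PSIS-LOO from a (draws x observations) pointwise log-likelihood.

    For each observation the importance ratios are 1/p(y_i | draw); the
    largest ``tail_frac`` of ratios are replaced by expected order
    statistics of a fitted generalised-Pareto distribution and truncated at
    the raw maximum.  Flags a warning when more than 10% of observations
    have Pareto-k > 0.7.
    """
    loglik = np.asarray(loglik, dtype=float)
    if not np.all(np.isfinite(loglik)):
        raise ValueError("pointwise log-likelihood matrix must be finite")
    S, n = loglik.shape
    pointwise = np.empty(n)
    ks = np.empty(n)
    for i in range(n):
        lw, k = _psis_smooth(-loglik[:, i], tail_frac)
        lw = lw - _logsumexp(lw)
        pointwise[i] = _logsumexp(lw + loglik[:, i])
        ks[i] = k
    warn = bool(np.mean(ks > 0.7) > 0.10)
    if warn:
        warnings.warn(
            f"{np.mean(ks > 0.7):.0%} of observations have Pareto-k > 0.7; "
            "PSIS-LOO may be unreliable",
            stacklevel=2,
        )
    return LooResult(pointwise=pointwise, pareto_k=ks, warn=warn, n_draws=S)


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.sum(np.exp(x - m))))


def select_model(
    full: tuple[ModelSpec, LooResult],
    candidates: list[tuple[ModelSpec, LooResult]],
) -> tuple[ModelSpec, dict]:
    """Choose the most parsimonious model with the lowest LOOIC.

    Any model whose elpd is within one standard error (of the pairwise
    pointwise difference) of the best model's is considered tied with it;
    ties resolve toward fewer coefficients.  Returns the chosen spec and a
    comparison report.
    """
    models = [full] + list(candidates)
    n_obs = {loo.n_obs for _, loo in models}
    if len(n_obs) != 1:
        raise ValueError("models were evaluated on different observation sets")
    best_idx = int(np.argmin([loo.looic for _, loo in models]))
    best_loo = models[best_idx][1]
    tied = []
    for i, (spec, loo) in enumerate(models):
        diff, se = best_loo.elpd_diff(loo)
        if i == best_idx or diff <= se:
            tied.append(i)
    chosen = min(tied, key=lambda i: (models[i][0].n_coefficients(), i))
    report = {
        "looic": [loo.looic for _, loo in models],
        "elpd": [loo.elpd for _, loo in models],
        "n_coefficients": [spec.n_coefficients() for spec, _ in models],
        "best_index": best_idx,
        "chosen_index": chosen,
    }
    return models[chosen][0], report
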