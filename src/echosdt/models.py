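"""Bayesian estimation of the per-participant SDT models.

Two models are fitted to each participant's trial-level 0/1 responses,
both with the Bernoulli-probit likelihood of :func:`echosdt.sdt.p_yes` and
independent weakly informative Normal(0, 3) priors on every parameter:

* **Categorical model** ("Model 1"): a separate (d', c) pair for each of
  the 2 tasks x 10 distances — 40 free parameters, no assumption about how
  sensitivity varies with distance. Its per-cell posteriors play the role
  of "observed" data points.
* **Exponential model** ("Model 2"): d' decays (or grows) exponentially in
  distance X, a fixed proportional change per meter —
  d'_det(X) = alpha0 * exp(alpha1 * X), d'_loc(X) = beta0 * exp(beta1 * X) —
  with one distance-constant bias per task (c0 detection, c1 localization):
  6 free parameters.

Because responses are conditionally independent given the parameters, the
categorical posterior factorizes over (task, distance) cells; each cell is
sampled as an independent 2-D problem, which is exact and fast. Sampling
uses the affine-invariant ensemble sampler (emcee); walkers serve as
chains for split-R-hat and effective-sample-size diagnostics (arviz).
Posteriors are summarised by the median and the 95% highest-posterior-
density (HPD) interval, the narrowest interval holding the stated mass.

Unlike the closed-form estimators, these posteriors remain proper when a
cell has an empirical hit rate of exactly 0 or 1: the prior regularizes
the estimate to a finite value with a wide interval.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import emcee
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .design import TASK_DETECTION, TASK_LOCALIZATION, signal_indicator, response_indicator

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "FitResult",
    "PRIOR_SD",
    "EXPONENTIAL_PARAMS",
    "cell_counts",
    "counts_log_likelihood",
    "fit_categorical",
    "fit_exponential",
    "hpd_interval",
    "task_contrasts",
    "bias_table",
]

#: Standard deviation of the common Normal(0, sd) prior on every parameter.
PRIOR_SD = 3.0

#: Parameter order of the exponential (Model-2) fit.
EXPONENTIAL_PARAMS = ("alpha0", "alpha1", "beta0", "beta1", "c0", "c1")

# Bernoulli probabilities are clamped here inside the log-likelihood for
# numerical safety; the bound never binds at prior-plausible parameters.
_P_FLOOR = 1e-12


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    ``walkers * draws`` post-warmup draws are retained. Defaults (via
    :meth:`for_categorical` / :meth:`for_exponential`) are sized so that a
    full two-model participant fit runs in well under a minute while
    clearing the convergence bar of split-R-hat <= ``rhat_max`` and
    ESS >= ``ess_min`` on every parameter.
    """

    walkers: int = 16
    warmup: int = 1000
    draws: int = 2000
    seed: int = 0
    rhat_max: float = 1.01
    ess_min: float = 400.0

    @classmethod
    def for_categorical(cls, seed: int = 0) -> "SamplerConfig":
        # each (task, distance) cell is an independent 2-D posterior
        return cls(walkers=16, warmup=500, draws=1200, seed=seed)

    @classmethod
    def for_exponential(cls, seed: int = 0) -> "SamplerConfig":
        # one joint 6-D posterior; longer chains for split-R-hat <= 1.01
        return cls(walkers=16, warmup=1000, draws=4000, seed=seed)


@dataclass
class FitResult:
    """Posterior of one model for one participant.

    ``draws`` maps parameter name -> (chains, draws) array of post-warmup
    samples. ``summaries`` is indexed by parameter with columns
    ``median, hpd_low, hpd_high, rhat, ess``. ``converged`` is False when
    any parameter misses the diagnostic thresholds (the fit is flagged,
    never silently accepted).
    """

    model_id: str
    participant_id: str
    draws: dict[str, np.ndarray]
    summaries: pd.DataFrame
    converged: bool
    sampler_meta: dict

    def draws_frame(self) -> pd.DataFrame:
        """All posterior draws as a flat column-per-parameter table."""
        return pd.DataFrame({k: v.ravel() for k, v in self.draws.items()})

    def to_dict(self) -> dict:
        """JSON-serializable summary (draws excluded)."""
        return {
            "model_id": self.model_id,
            "participant_id": self.participant_id,
            "converged": bool(self.converged),
            "sampler_meta": self.sampler_meta,
            "summaries": (
                self.summaries.reset_index()
                .rename(columns={"index": "parameter"})
                .to_dict(orient="records")
            ),
        }


# ---------------------------------------------------------------------------
# Likelihood machinery (sufficient statistics per (task, distance) cell)
# ---------------------------------------------------------------------------

def cell_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(task, distance) response counts.

    Returns a frame indexed by (task, distance_m) with columns
    ``n_signal, yes_signal, n_noise, yes_noise`` — the sufficient
    statistics of the Bernoulli-probit likelihood.
    """
    if trials["response"].isna().any():
        raise ValueError("trials contain unset responses; simulate or load responses first")
    s = signal_indicator(trials)
    y = response_indicator(trials)
    df = pd.DataFrame(
        {
            "task": trials["task"].to_numpy(),
            "distance_m": trials["distance_m"].to_numpy(dtype=float),
            "n_signal": s,
            "yes_signal": s * y,
            "n_noise": 1 - s,
            "yes_noise": (1 - s) * y,
        }
    )
    return df.groupby(["task", "distance_m"]).sum().sort_index()


def counts_log_likelihood(
    n_signal, yes_signal, n_noise, yes_noise, d_prime, criterion
):
    """Bernoulli-probit log-likelihood from cell counts (broadcasting).

    Hit probability 1 - Phi(c - d'/2), false-alarm probability
    1 - Phi(c + d'/2); probabilities clamped away from 0/1 by 1e-12.
    """
    p1 = np.clip(ndtr(d_prime / 2.0 - criterion), _P_FLOOR, 1.0 - _P_FLOOR)
    p0 = np.clip(ndtr(-d_prime / 2.0 - criterion), _P_FLOOR, 1.0 - _P_FLOOR)
    return (
        yes_signal * np.log(p1)
        + (n_signal - yes_signal) * np.log1p(-p1)
        + yes_noise * np.log(p0)
        + (n_noise - yes_noise) * np.log1p(-p0)
    )


def _log_prior(theta: np.ndarray) -> np.ndarray:
    return -0.5 * np.sum(theta * theta, axis=-1) / (PRIOR_SD**2)


def _single_participant(trials: pd.DataFrame) -> str:
    pids = trials["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(
            f"fit expects trials from exactly one participant, got {sorted(map(str, pids))}"
        )
    return str(pids[0])


def _require_complete_cells(counts: pd.DataFrame) -> None:
    tasks = sorted({t for t, _ in counts.index})
    if set(tasks) != {TASK_DETECTION, TASK_LOCALIZATION}:
        raise ValueError(
            f"fit requires trials from both tasks; found only {tasks}"
        )
    distances = sorted({x for _, x in counts.index})
    for t in (TASK_DETECTION, TASK_LOCALIZATION):
        for x in distances:
            if (t, x) not in counts.index:
                raise ValueError(f"empty cell: no trials for task={t!r} at {x:.2f} m")


def _fit_seed(seed: int, participant_id: str, model_code: int, unit: int) -> int:
    ss = np.random.SeedSequence(
        [int(seed), zlib.crc32(participant_id.encode("utf-8")), model_code, unit]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _run_ensemble(
    log_prob, center: np.ndarray, ndim: int, config: SamplerConfig, seed: int
) -> np.ndarray:
    """Run emcee from a tight ball around ``center``; return (chains, draws, ndim)."""
    rng = np.random.default_rng(seed)
    p0 = np.asarray(center, float) + 0.05 * rng.standard_normal((config.walkers, ndim))
    # differential-evolution moves mix far better than the default stretch
    # move on these correlated low-dimensional posteriors
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        config.walkers, ndim, log_prob, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, config.warmup + config.draws, progress=False)
    return np.moveaxis(sampler.get_chain(discard=config.warmup), 0, 1)


def _diagnostics(arr: np.ndarray) -> tuple[float, float]:
    import arviz as az

    return float(az.rhat(arr)), float(az.ess(arr))


def _summarize(draws: dict[str, np.ndarray], config: SamplerConfig) -> tuple[pd.DataFrame, bool]:
    rows = {}
    converged = True
    for name, arr in draws.items():
        lo, hi = hpd_interval(arr, 0.95)
        rhat, ess = _diagnostics(arr)
        rows[name] = {
            "median": float(np.median(arr)),
            "hpd_low": lo,
            "hpd_high": hi,
            "rhat": rhat,
            "ess": ess,
        }
        if not (np.isfinite(rhat) and np.isfinite(ess)):
            converged = False
        elif rhat > config.rhat_max or ess < config.ess_min:
            converged = False
    return pd.DataFrame.from_dict(rows, orient="index"), converged


# ---------------------------------------------------------------------------
# Model 1: categorical distance
# ---------------------------------------------------------------------------

def _cell_log_post(n1: float, k1: float, n0: float, k0: float):
    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        d, c = theta[..., 0], theta[..., 1]
        return counts_log_likelihood(n1, k1, n0, k0, d, c) + _log_prior(theta)

    return log_post


def _cell_start(n1: float, k1: float, n0: float, k0: float) -> np.ndarray:
    # smoothed closed-form estimate; falls back to the prior mode when one
    # stimulus class is absent from the cell
    if n1 == 0 or n0 == 0:
        return np.zeros(2)
    zh = ndtri((k1 + 0.5) / (n1 + 1.0))
    zf = ndtri((k0 + 0.5) / (n0 + 1.0))
    return np.array([zh - zf, -0.5 * (zh + zf)])


def fit_categorical(trials: pd.DataFrame, config: SamplerConfig | None = None) -> FitResult:
    """Fit the categorical (per-cell d', c) model to one participant.

    Every (task, distance) cell contributes an independent 2-parameter
    posterior; with the default 10-distance design the result has 40
    parameters. Deterministic given ``config.seed``.
    """
    config = config if config is not None else SamplerConfig.for_categorical()
    pid = _single_participant(trials)
    counts = cell_counts(trials)
    _require_complete_cells(counts)
    distances = sorted({x for _, x in counts.index})

    draws: dict[str, np.ndarray] = {}
    for j, ((task, x), row) in enumerate(counts.iterrows()):
        n1, k1, n0, k0 = (
            float(row["n_signal"]),
            float(row["yes_signal"]),
            float(row["n_noise"]),
            float(row["yes_noise"]),
        )
        chain = _run_ensemble(
            _cell_log_post(n1, k1, n0, k0),
            _cell_start(n1, k1, n0, k0),
            ndim=2,
            config=config,
            seed=_fit_seed(config.seed, pid, 1, j),
        )
        draws[f"d_prime[{task},{x:.2f}]"] = chain[:, :, 0]
        draws[f"criterion[{task},{x:.2f}]"] = chain[:, :, 1]

    summaries, converged = _summarize(draws, config)
    if not converged:
        logger.warning("categorical fit for %s flagged as not converged", pid)
    meta = {
        "distances": [float(x) for x in distances],
        "chains": config.walkers,
        "draws_per_chain": config.draws,
        "warmup": config.warmup,
        "seed": config.seed,
        "sampler": "emcee ensemble",
    }
    return FitResult("categorical", pid, draws, summaries, converged, meta)


# ---------------------------------------------------------------------------
# Model 2: exponential distance
# ---------------------------------------------------------------------------

def _exponential_log_post(counts: pd.DataFrame):
    is_loc = np.array([t == TASK_LOCALIZATION for t, _ in counts.index])
    x = np.array([d for _, d in counts.index], float)
    n1 = counts["n_signal"].to_numpy(float)
    k1 = counts["yes_signal"].to_numpy(float)
    n0 = counts["n_noise"].to_numpy(float)
    k0 = counts["yes_noise"].to_numpy(float)

    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        a0, a1, b0, b1, c0, c1 = (theta[..., i, None] for i in range(6))
        with np.errstate(over="ignore"):
            d = np.where(is_loc, b0 * np.exp(b1 * x), a0 * np.exp(a1 * x))
        c = np.where(is_loc, c1, c0)
        ll = counts_log_likelihood(n1, k1, n0, k0, d, c).sum(axis=-1)
        return ll + _log_prior(theta)

    return log_post


def fit_exponential(trials: pd.DataFrame, config: SamplerConfig | None = None) -> FitResult:
    """Fit the exponential-in-distance model (6 parameters) to one participant.

    d'(X) = alpha0*exp(alpha1*X) for detection and beta0*exp(beta1*X) for
    localization; one bias per task (c0, c1) shared across distances.
    Walkers start from a Nelder-Mead posterior-mode search.
    """
    config = config if config is not None else SamplerConfig.for_exponential()
    pid = _single_participant(trials)
    counts = cell_counts(trials)
    _require_complete_cells(counts)
    log_post = _exponential_log_post(counts)

    opt = minimize(
        lambda th: -float(log_post(th[None, :])[0]),
        x0=np.array([1.0, -0.5, 1.0, -0.5, 0.0, 0.0]),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    chain = _run_ensemble(
        log_post, opt.x, ndim=6, config=config, seed=_fit_seed(config.seed, pid, 2, 0)
    )
    draws = {name: chain[:, :, i] for i, name in enumerate(EXPONENTIAL_PARAMS)}
    summaries, converged = _summarize(draws, config)
    if not converged:
        logger.warning("exponential fit for %s flagged as not converged", pid)
    meta = {
        "distances": sorted({float(d) for _, d in counts.index}),
        "chains": config.walkers,
        "draws_per_chain": config.draws,
        "warmup": config.warmup,
        "seed": config.seed,
        "sampler": "emcee ensemble",
    }
    return FitResult("exponential", pid, draws, summaries, converged, meta)


# ---------------------------------------------------------------------------
# Posterior summaries and derived contrasts
# ---------------------------------------------------------------------------

def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws.

    The highest-posterior-density interval of a (unimodal) sample: among
    all windows of ceil(mass * n) consecutive sorted draws, the shortest.
    Requires at least 100 draws.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(samples, float).ravel())
    n = x.size
    window = int(math.ceil(mass * n))
    if n < 100 or window >= n + 1:
        raise ValueError(f"need at least 100 draws (and a window <= n); got n={n}")
    widths = x[window - 1 :] - x[: n - window + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + window - 1])


def _interval_row(draws: np.ndarray, mass: float = 0.95) -> dict:
    lo, hi = hpd_interval(draws, mass)
    return {"median": float(np.median(draws)), "hpd_low": lo, "hpd_high": hi}


def task_contrasts(fit: FitResult) -> pd.DataFrame:
    """Per-distance detection-minus-localization d' difference.

    Computed draw-wise from the categorical fit (the median of differences,
    not the difference of medians), with 95% HPD intervals.
    """
    if fit.model_id != "categorical":
        raise ValueError(f"task_contrasts requires a categorical fit, got {fit.model_id!r}")
    rows = []
    for x in fit.sampler_meta["distances"]:
        diff = (
            fit.draws[f"d_prime[{TASK_DETECTION},{x:.2f}]"]
            - fit.draws[f"d_prime[{TASK_LOCALIZATION},{x:.2f}]"]
        )
        rows.append({"distance_m": float(x), **_interval_row(diff)})
    return pd.DataFrame(rows)


def bias_table(fit1: FitResult, fit2: FitResult) -> pd.DataFrame:
    """Response-bias summary across the two models for one participant.

    Categorical rows average the 10 per-distance criterion draws within
    task (draw-wise) before taking medians and HPDs; exponential rows use
    the single per-task bias parameters. The between-task difference row
    is the draw-wise c_detection - c_localization.
    """
    if fit1.model_id != "categorical" or fit2.model_id != "exponential":
        raise ValueError("bias_table expects (categorical fit, exponential fit)")
    if fit1.participant_id != fit2.participant_id:
        raise ValueError(
            f"participant mismatch: {fit1.participant_id!r} vs {fit2.participant_id!r}"
        )
    rows = []

    per_task = {}
    for task in (TASK_DETECTION, TASK_LOCALIZATION):
        stack = np.stack(
            [
                fit1.draws[f"criterion[{task},{x:.2f}]"]
                for x in fit1.sampler_meta["distances"]
            ]
        )
        per_task[task] = stack.mean(axis=0)
    for task in (TASK_DETECTION, TASK_LOCALIZATION):
        rows.append(
            {"model": "categorical", "quantity": f"c_{task}", **_interval_row(per_task[task])}
        )
    rows.append(
        {
            "model": "categorical",
            "quantity": "c_difference",
            **_interval_row(per_task[TASK_DETECTION] - per_task[TASK_LOCALIZATION]),
        }
    )

    c0, c1 = fit2.draws["c0"], fit2.draws["c1"]
    rows.append({"model": "exponential", "quantity": f"c_{TASK_DETECTION}", **_interval_row(c0)})
    rows.append({"model": "exponential", "quantity": f"c_{TASK_LOCALIZATION}", **_interval_row(c1)})
    rows.append({"model": "exponential", "quantity": "c_difference", **_interval_row(c0 - c1)})

    out = pd.DataFrame(rows)
    out.insert(0, "participant_id", fit1.participant_id)
    return out
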