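"""Monte-Carlo robustness procedures for the GARP analysis.

Three seeded simulations accompany the revealed-preference test:

* :func:`random_chooser_false_positive` -- Bronars-style power analysis: the
  probability that a chooser drawing its pump share uniformly on [0, 1] at
  every budget passes GARP on a given ensemble.  A high pass probability
  means the ensemble is a weak test; adding intersecting budget lines makes
  it more stringent.
* :func:`gaussian_resample_violation_probability` -- sampling-error check:
  resample each budget's mean share from Normal(mean, SEM) and estimate the
  probability of observing at least one violation.
* :func:`model_maximization_probability` -- model-predicted performance: add
  share noise to a fitted price-ratio curve and estimate the probability of
  passing GARP on a (possibly different) ensemble.

All three map shares to bundles through proportional consumption, under
which every simulated bundle lies on its budget line and own expenditure is
exactly 1; the GARP check is a vectorized closure over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import BudgetSpec
from .garp import DEFAULT_EXPENDITURE_RTOL

__all__ = [
    "SimulationResult",
    "batch_violation_counts",
    "random_chooser_false_positive",
    "gaussian_resample_violation_probability",
    "model_maximization_probability",
]

logger = logging.getLogger(__name__)

_CHUNK = 1 << 14


@dataclass(frozen=True)
class SimulationResult:
    """Estimated probability with its binomial 95% interval and provenance."""

    probability: float
    n_sims: int
    seed: Optional[int]
    ci95: tuple[float, float]
    n_success: int
    detail: Optional[np.ndarray] = None  # per-replicate violation counts, capped

    def to_dict(self) -> dict:
        return {
            "probability": self.probability,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "ci95": list(self.ci95),
            "n_success": self.n_success,
        }


def _binomial_ci95(k: int, n: int) -> tuple[float, float]:
    """Clopper-Pearson exact 95% interval for a binomial proportion."""
    alpha = 0.05
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _result(successes: int, n_sims: int, seed, detail) -> SimulationResult:
    return SimulationResult(
        probability=successes / n_sims,
        n_sims=n_sims,
        seed=seed,
        ci95=_binomial_ci95(successes, n_sims),
        n_success=successes,
        detail=detail,
    )


def batch_violation_counts(
    shares: np.ndarray,
    ensemble: Sequence[BudgetSpec],
    tol: float = DEFAULT_EXPENDITURE_RTOL,
) -> np.ndarray:
    """GARP violation counts for many share vectors on one ensemble.

    ``shares`` is an (n_rep, K) array of pump shares; each row is mapped to
    proportional-consumption bundles (own expenditure exactly 1) and checked
    for GARP violations.  Returns the per-row count of ordered violating
    pairs; zero means the row passes.
    """
    shares = np.atleast_2d(np.asarray(shares, dtype=float))
    K = len(ensemble)
    if shares.shape[1] != K:
        raise ValueError("one share per budget required")
    d_H = np.array([b.d_H for b in ensemble])
    d_M = np.array([b.d_M for b in ensemble])
    p_H, p_M = 1.0 / d_H, 1.0 / d_M
    counts = np.empty(shares.shape[0], dtype=np.int64)
    for start in range(0, shares.shape[0], _CHUNK):
        S = shares[start : start + _CHUNK]
        qH = S * d_H  # (n, K)
        qM = (1.0 - S) * d_M
        # C[n, i, j] = p_i . x_j ; own expenditure is exactly 1
        C = p_H[:, None] * qH[:, None, :] + p_M[:, None] * qM[:, None, :]
        R = (C <= 1.0 + tol).astype(np.uint8)
        P0 = C < 1.0 - tol
        # transitive closure by repeated boolean squaring
        for _ in range(max(1, int(np.ceil(np.log2(K))))):
            R = np.minimum(R + np.matmul(R, R), 1)
        viol = R.astype(bool) & P0.transpose(0, 2, 1)
        idx = np.arange(K)
        viol[:, idx, idx] = False
        counts[start : start + S.shape[0]] = viol.sum(axis=(1, 2))
    return counts


def _draw_shares_normal(
    rng: np.random.Generator,
    means: np.ndarray,
    sds: np.ndarray,
    n_sims: int,
    out_of_range: str,
) -> np.ndarray:
    """Normal draws per budget, kept in [0, 1] by clipping or resampling."""
    if out_of_range == "resample":
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(sds > 0, (0.0 - means) / sds, -np.inf)
            b = np.where(sds > 0, (1.0 - means) / sds, np.inf)
        draws = stats.truncnorm.rvs(
            a, b, loc=means, scale=np.where(sds > 0, sds, 1.0),
            size=(n_sims, means.size), random_state=rng,
        )
        return np.where(sds > 0, draws, means)
    if out_of_range != "clip":
        raise ValueError("out_of_range must be 'clip' or 'resample'")
    draws = rng.normal(means, sds, size=(n_sims, means.size))
    clipped = ((draws < 0) | (draws > 1)).mean()
    if clipped > 0.01:
        logger.info("%.2f%% of share draws clipped to [0, 1]", 100 * clipped)
    return np.clip(draws, 0.0, 1.0)


def random_chooser_false_positive(
    ensemble: Sequence[BudgetSpec],
    n_sims: int = 10**6,
    seed: Optional[int] = None,
    keep_detail: int = 0,
) -> SimulationResult:
    """Probability that a uniformly random chooser passes GARP on an ensemble.

    Per replicate the share f_H at every budget is drawn independently from
    Uniform(0, 1) and mapped to a bundle on the budget line; the estimate is
    the fraction of replicates with zero violations.  This false-positive
    probability is 1.0 on ensembles of mutually non-crossing budget lines
    and decreases as intersecting lines are added.
    """
    if len(ensemble) < 2:
        raise ValueError("at least 2 budgets are required")
    rng = np.random.default_rng(seed)
    shares = rng.uniform(0.0, 1.0, size=(n_sims, len(ensemble)))
    counts = batch_violation_counts(shares, ensemble)
    detail = counts[:keep_detail].copy() if keep_detail else None
    return _result(int((counts == 0).sum()), n_sims, seed, detail)


def gaussian_resample_violation_probability(
    means: Sequence[float],
    sems: Sequence[float],
    ensemble: Sequence[BudgetSpec],
    n_sims: int = 10**6,
    seed: Optional[int] = None,
    out_of_range: str = "clip",
    keep_detail: int = 0,
) -> SimulationResult:
    """Probability of at least one GARP violation under sampling error.

    Each budget's share is drawn from Normal(mean, SEM) kept in [0, 1]
    (clipped by default, redrawn if ``out_of_range='resample'``), mapped to
    a bundle, and checked; the estimate is the fraction of replicates with
    one or more violations.
    """
    means = np.asarray(means, dtype=float)
    sems = np.asarray(sems, dtype=float)
    if means.size != len(ensemble) or sems.size != len(ensemble):
        raise ValueError("one (mean, SEM) pair per budget required")
    if (sems < 0).any():
        raise ValueError("SEMs must be non-negative")
    if ((means < 0) | (means > 1)).any():
        raise ValueError("mean shares must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shares = _draw_shares_normal(rng, means, sems, n_sims, out_of_range)
    counts = batch_violation_counts(shares, ensemble)
    detail = counts[:keep_detail].copy() if keep_detail else None
    return _result(int((counts > 0).sum()), n_sims, seed, detail)


def model_maximization_probability(
    curve: Callable[[float], float],
    ensemble: Sequence[BudgetSpec],
    noise_sd: float,
    n_sims: int = 10**6,
    seed: Optional[int] = None,
    out_of_range: str = "clip",
    keep_detail: int = 0,
) -> SimulationResult:
    """Probability that a price-ratio-curve chooser passes GARP under noise.

    Shares are ``curve(r_i) + Normal(0, noise_sd)`` kept in [0, 1]; the
    estimate is the fraction of replicates with zero violations.  With zero
    noise and a monotone curve the probability is 1; as noise grows it
    approaches the random-chooser false-positive rate of the ensemble.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    means = np.clip([float(curve(b.r)) for b in ensemble], 0.0, 1.0)
    rng = np.random.default_rng(seed)
    shares = _draw_shares_normal(
        rng, means, np.full(len(ensemble), noise_sd), n_sims, out_of_range
    )
    counts = batch_violation_counts(shares, ensemble)
    detail = counts[:keep_detail].copy() if keep_detail else None
    return _result(int((counts == 0).sum()), n_sims, seed, detail)
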