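"""Utility functions over the two foods and CES estimation by two-limit tobit.

The linear (perfect-substitute) utility is ``U = beta*x + (1-beta)*y``; its
constant exchange rate ``beta/(1-beta)`` forces corner solutions on any
budget line.  The constant-elasticity-of-substitution (CES) utility

    U(q_H, q_M) = (beta * q_H**rho + (1-beta) * q_M**rho) ** (1/rho)

relaxes this: rho = 1 recovers perfect substitutes, -0.5 < rho < 1 models
imperfect substitutes (diminishing marginal utility), and rho << -0.5
approaches perfect complements.  Maximizing CES utility on the normalized
budget ``p_H q_H + p_M q_M = 1`` gives an interior optimum with expenditure
share on H

    s = z / (1 + z),    z = (p_H/p_M) * (beta*p_M / ((1-beta)*p_H)) ** (1/(1-rho)),

which equals the pump share f_H.  The parameters (beta, rho) are estimated
from per-worm shares by two-limit tobit maximum likelihood: the latent share
is the CES optimum plus i.i.d. normal error, observed shares are censored at
0 and 1, interior observations contribute a normal density term and boundary
observations normal tail probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .core import BudgetSpec
from .garp import PriceQuantityDataset

__all__ = [
    "LinearUtilityParams",
    "CESParams",
    "linear_utility",
    "ces_utility",
    "cobb_douglas_utility",
    "ces_optimal_share",
    "CESTobitModel",
    "CESTobitResults",
    "fit_ces_tobit",
    "predict_ensemble_choices",
    "alternative_maximand_predictions",
]


@dataclass(frozen=True)
class LinearUtilityParams:
    """Weight of the perfect-substitute utility U = beta*x + (1-beta)*y."""

    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    @property
    def exchange_rate(self) -> float:
        """Units of y compensating one unit of x, beta/(1-beta)."""
        if self.beta == 1.0:
            raise ZeroDivisionError("exchange rate undefined at beta = 1")
        return self.beta / (1.0 - self.beta)


@dataclass(frozen=True)
class CESParams:
    """CES parameters: weight beta in (0, 1), curvature rho <= 1, rho != 0."""

    beta: float
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.rho == 0.0:
            raise ValueError(
                "rho = 0 is the Cobb-Douglas limit; use cobb_douglas_utility"
            )
        if self.rho > 1.0:
            raise ValueError("rho must be <= 1")


def linear_utility(q_H, q_M, beta: float):
    """Perfect-substitute utility beta*q_H + (1-beta)*q_M."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    q_H = np.asarray(q_H, dtype=float)
    q_M = np.asarray(q_M, dtype=float)
    if (q_H < 0).any() or (q_M < 0).any():
        raise ValueError("quantities must be non-negative")
    out = beta * q_H + (1.0 - beta) * q_M
    return out if out.ndim else float(out)


def ces_utility(q_H, q_M, params: CESParams):
    """CES utility (beta*q_H**rho + (1-beta)*q_M**rho)**(1/rho).

    For rho < 0 a zero quantity gives utility 0 (the mathematical limit).
    """
    beta, rho = params.beta, params.rho
    q_H = np.asarray(q_H, dtype=float)
    q_M = np.asarray(q_M, dtype=float)
    if (q_H < 0).any() or (q_M < 0).any():
        raise ValueError("quantities must be non-negative")
    if rho < 0:
        zero = (q_H == 0) | (q_M == 0)
        with np.errstate(divide="ignore"):
            inner = np.where(
                zero, 1.0, beta * q_H**rho + (1.0 - beta) * q_M**rho
            )
        out = np.where(zero, 0.0, inner ** (1.0 / rho))
    else:
        out = (beta * q_H**rho + (1.0 - beta) * q_M**rho) ** (1.0 / rho)
    return out if out.ndim else float(out)


def cobb_douglas_utility(q_H, q_M, beta: float):
    """Cobb-Douglas utility q_H**beta * q_M**(1-beta), the rho -> 0 limit of CES."""
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    q_H = np.asarray(q_H, dtype=float)
    q_M = np.asarray(q_M, dtype=float)
    if (q_H < 0).any() or (q_M < 0).any():
        raise ValueError("quantities must be non-negative")
    out = q_H**beta * q_M ** (1.0 - beta)
    return out if out.ndim else float(out)


def ces_optimal_share(params: CESParams, p_H, p_M, warn_corner: bool = True):
    """Expenditure share on H that maximizes CES utility on the budget line.

    The tangency (first-order) condition of maximizing the CES utility
    subject to ``p_H q_H + p_M q_M = 1`` gives

        z = (p_H/p_M) * (beta*p_M / ((1-beta)*p_H)) ** (1/(1-rho)),
        share = z / (1 + z)  in (0, 1).

    This expenditure share equals the pump share f_H.  At rho = 1 (perfect
    substitutes) the optimum is a corner: the share is 1 when
    ``beta * d_H > (1-beta) * d_M`` (i.e. beta/p_H > (1-beta)/p_M), 0 when
    the inequality reverses, and 0.5 at exact indifference.
    """
    p_H = np.asarray(p_H, dtype=float)
    p_M = np.asarray(p_M, dtype=float)
    if (p_H <= 0).any() or (p_M <= 0).any():
        raise ValueError("prices must be positive")
    beta, rho = params.beta, params.rho
    if rho >= 1.0:
        if warn_corner:
            warnings.warn(
                "rho >= 1: perfect substitutes imply a corner solution",
                stacklevel=2,
            )
        # Corner solution: compare utility per pump of the two corners.
        uH = beta / p_H
        uM = (1.0 - beta) / p_M
        out = np.where(uH > uM, 1.0, np.where(uH < uM, 0.0, 0.5))
        return out if out.ndim else float(out)
    # share = z/(1+z) computed in log space to stay finite as rho -> 1
    log_z = np.log(p_H / p_M) + np.log(beta * p_M / ((1.0 - beta) * p_H)) / (1.0 - rho)
    out = special.expit(log_z)
    return out if out.ndim else float(out)


class CESTobitModel:
    """Two-limit tobit model of per-worm pump shares around the CES optimum.

    The latent share on budget i is ``s_i* = g(beta, rho; p_i) + eps``,
    ``eps ~ N(0, sigma^2)`` i.i.d., where g is :func:`ces_optimal_share`; the
    observed share is censored at 0 and 1.  Log-likelihood terms:

    * interior (0 < f < 1):  log phi((f - mu)/sigma) - log sigma
    * at 0:                  log Phi((0 - mu)/sigma)
    * at 1:                  log Phi((mu - 1)/sigma)

    Parameters
    ----------
    shares : observed pump shares f_H in [0, 1], one per observation.
    prices : (n_obs, 2) array of (p_H, p_M) per observation.
    """

    BETA_BOUNDS = (0.01, 0.99)
    RHO_BOUNDS = (-5.0, 0.999)
    SIGMA_BOUNDS = (1e-4, 1.0)

    def __init__(self, shares: Sequence[float], prices: np.ndarray):
        f = np.asarray(shares, dtype=float)
        p = np.atleast_2d(np.asarray(prices, dtype=float))
        if p.shape != (f.size, 2):
            raise ValueError("prices must be an (n_obs, 2) array matching shares")
        if ((f < 0) | (f > 1)).any():
            raise ValueError("shares must lie in [0, 1]")
        if (p <= 0).any():
            raise ValueError("prices must be positive")
        if np.unique(p, axis=0).shape[0] < 3:
            raise ValueError("at least 3 distinct budgets are required")
        interior = (f > 0) & (f < 1)
        if not interior.any():
            raise ValueError("degenerate fit: all shares censored at 0 or 1")
        self.shares = f
        self.prices = p
        self._interior = interior
        self._at_zero = f == 0
        self._at_one = f == 1

    @classmethod
    def from_observations(cls, observations) -> "CESTobitModel":
        """Build from an iterable of (BudgetSpec, f_H) pairs or ChoiceObservations."""
        shares, prices = [], []
        for obs in observations:
            if hasattr(obs, "budget"):  # ChoiceObservation
                shares.append(obs.f_H)
                prices.append([obs.budget.p_H, obs.budget.p_M])
            else:
                budget, f = obs
                shares.append(float(f))
                prices.append([budget.p_H, budget.p_M])
        return cls(np.array(shares), np.array(prices))

    @classmethod
    def from_dataframe(cls, table) -> "CESTobitModel":
        """Build from a choice table with columns d_H, d_M, n_H, n_M."""
        f = table["n_H"] / (table["n_H"] + table["n_M"])
        p = np.column_stack([1.0 / table["d_H"], 1.0 / table["d_M"]])
        return cls(f.to_numpy(), p)

    def loglike(self, params: Sequence[float]) -> float:
        beta, rho, sigma = params
        mu = ces_optimal_share(
            CESParams(beta=beta, rho=rho if rho != 0 else 1e-12),
            self.prices[:, 0],
            self.prices[:, 1],
        )
        mu = np.asarray(mu)
        ll = 0.0
        if self._interior.any():
            z = (self.shares[self._interior] - mu[self._interior]) / sigma
            ll += np.sum(stats.norm.logpdf(z) - np.log(sigma))
        if self._at_zero.any():
            ll += np.sum(stats.norm.logcdf(-mu[self._at_zero] / sigma))
        if self._at_one.any():
            ll += np.sum(stats.norm.logcdf((mu[self._at_one] - 1.0) / sigma))
        return float(ll)

    def _negloglike(self, theta: np.ndarray) -> float:
        ll = self.loglike(theta)
        return np.inf if not np.isfinite(ll) else -ll

    def fit(self, n_starts: int = 6) -> "CESTobitResults":
        """Maximize the likelihood by bounded quasi-Newton from multiple starts.

        The likelihood can be multi-modal in rho, so at least five starts on
        a (beta, rho) grid are used; sigma starts at the residual scale of
        the best grid point.
        """
        bounds = [self.BETA_BOUNDS, self.RHO_BOUNDS, self.SIGMA_BOUNDS]
        beta0 = np.clip(np.mean(self.shares), 0.05, 0.95)
        starts = [
            (beta0, 0.5),
            (beta0, -0.5),
            (0.5, 0.3),
            (0.3, 0.8),
            (0.7, 0.8),
            (0.5, -2.0),
        ][: max(n_starts, 5)]
        sigma0 = float(np.clip(np.std(self.shares), 0.02, 0.5))
        best, diagnostics = None, []
        for b0, r0 in starts:
            sol = optimize.minimize(
                self._negloglike,
                x0=np.array([b0, r0, sigma0]),
                method="L-BFGS-B",
                bounds=bounds,
            )
            diagnostics.append(
                {"start": [b0, r0, sigma0], "fun": float(sol.fun),
                 "success": bool(sol.success), "message": str(sol.message)}
            )
            if np.isfinite(sol.fun) and (best is None or sol.fun < best.fun):
                best = sol
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                f"two-limit tobit fit failed from all starts: {diagnostics}"
            )
        beta, rho, sigma = best.x
        return CESTobitResults(
            model=self,
            params=CESParams(beta=float(beta), rho=float(rho)),
            sigma=float(sigma),
            loglik=-float(best.fun),
            n_obs=int(self.shares.size),
            converged=bool(best.success),
            diagnostics=diagnostics,
        )


@dataclass
class CESTobitResults:
    model: Optional[CESTobitModel]
    params: CESParams
    sigma: float
    loglik: float
    n_obs: int
    converged: bool
    diagnostics: list

    @property
    def beta(self) -> float:
        return self.params.beta

    @property
    def rho(self) -> float:
        return self.params.rho

    def bse(self) -> np.ndarray:
        """Standard errors from the numerical Hessian of the log-likelihood.

        NaN entries indicate a parameter at its bound or a singular Hessian.
        """
        theta = np.array([self.beta, self.rho, self.sigma])
        H = numdiff.approx_hess(theta, self.model.loglike)
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.inv(-H)
                var = np.diag(cov)
                return np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
            except np.linalg.LinAlgError:
                return np.full(3, np.nan)

    def predict_shares(self, ensemble: Sequence[BudgetSpec]) -> np.ndarray:
        return np.array(
            [ces_optimal_share(self.params, b.p_H, b.p_M) for b in ensemble]
        )

    def summary(self) -> str:
        se = self.bse() if self.model is not None else np.full(3, np.nan)
        return (
            "CES utility, two-limit tobit maximum likelihood\n"
            f"  n obs     : {self.n_obs}\n"
            f"  beta      : {self.beta:.4g}  (SE {se[0]:.3g})\n"
            f"  rho       : {self.rho:.4g}  (SE {se[1]:.3g})\n"
            f"  sigma     : {self.sigma:.4g}  (SE {se[2]:.3g})\n"
            f"  log-lik   : {self.loglik:.4f}\n"
            f"  converged : {self.converged}"
        )

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "rho": self.rho,
            "sigma": self.sigma,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def fit_ces_tobit(observations) -> CESTobitResults:
    """Convenience wrapper: ``CESTobitModel.from_observations(obs).fit()``."""
    return CESTobitModel.from_observations(observations).fit()


def predict_ensemble_choices(
    params: CESParams, ensemble: Sequence[BudgetSpec]
) -> PriceQuantityDataset:
    """Tangency bundles of a CES maximizer on each budget line.

    Each predicted bundle ``(s*d_H, (1-s)*d_M)`` lies exactly on its budget
    line and attains the tangency utility; the resulting dataset passes GARP
    with zero violations (utility maximizers cannot violate).
    """
    shares = np.array(
        [ces_optimal_share(params, b.p_H, b.p_M, warn_corner=False) for b in ensemble]
    )
    return PriceQuantityDataset.from_mean_shares(ensemble, shares)


def alternative_maximand_predictions(
    ensemble: Sequence[BudgetSpec],
    growth_rate_H: float = 0.50,
    growth_rate_M: float = 0.43,
) -> dict:
    """Per-budget shares predicted by three alternative maximization targets.

    * ``h_only`` -- maximize H-food intake: share 1 everywhere.
    * ``total_food`` -- maximize total intake: feed exclusively in the denser
      stream (share 1 where d_H > d_M, 0 where d_H < d_M, 0.5 at equality).
    * ``growth_potential`` -- maximize growth rate times density: share 1
      where ``g_H*d_H > g_M*d_M`` else 0; at equal densities H is preferred
      whenever g_H > g_M.

    All three predict corner solutions off the equality locus, which is how
    they are ruled out by the observed interior choices.  Default growth
    rates are the characteristic rates of worms on the two foods, 0.50 and
    0.43 per day.
    """
    if growth_rate_H <= 0 or growth_rate_M <= 0:
        raise ValueError("growth rates must be positive")
    d_H = np.array([b.d_H for b in ensemble])
    d_M = np.array([b.d_M for b in ensemble])
    total = np.where(d_H > d_M, 1.0, np.where(d_H < d_M, 0.0, 0.5))
    gH, gM = growth_rate_H * d_H, growth_rate_M * d_M
    growth = np.where(
        gH > gM, 1.0, np.where(gH < gM, 0.0, 1.0 if growth_rate_H > growth_rate_M else 0.5)
    )
    return {
        "h_only": np.ones(len(ensemble)),
        "total_food": total,
        "growth_potential": growth,
    }
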