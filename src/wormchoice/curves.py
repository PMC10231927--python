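"""Descriptive curve fits: constant-elasticity demand and the price-ratio curve.

Two curves summarize the assay.  The *demand curve* relates mean consumption
of one food to its own price,

    q(p) = A * p**epsilon,

with constant elasticity ``epsilon`` (expected < 0 for an ordinary good); it
is fit by ordinary least squares in log10-log10 space, where the model is
exactly linear.  The *price-ratio curve* relates the pump share f_H to the
log price ratio ``r = log10(d_H / d_M)`` through an exponential sigmoid

    f_H(r) = 1 / (1 + 10 ** (-(r - r0) / k)),

where ``r0`` is the indifference point (f_H(r0) = 0.5) and ``k`` sets the
dynamic range.  The sigmoid is bounded in (0, 1) like f_H itself and is
strictly increasing for k > 0, which is the property that guarantees GARP
adherence of its deterministic choices.

Both fits follow the statsmodels pattern: a Model object built from data
whose ``fit()`` returns a Results object carrying estimates, uncertainties
and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize

__all__ = [
    "DemandModel",
    "DemandResults",
    "PriceRatioSigmoidModel",
    "SigmoidResults",
    "PiecewiseLinearCurve",
    "sigmoid",
    "fit_demand",
    "fit_price_ratio_sigmoid",
    "substitutes_slope",
    "SlopeEstimate",
]


def sigmoid(r, r0: float, k: float):
    """Exponential sigmoid price-ratio curve, f_H(r) in (0, 1)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(over="ignore"):  # saturates cleanly to 0/1
        out = 1.0 / (1.0 + 10.0 ** (-(r - r0) / k))
    return out if out.ndim else float(out)


class DemandModel:
    """Constant-elasticity demand model ``q = A * p**epsilon``.

    Fit by OLS of log10(q) on log10(p): the elasticity is the slope and
    ``A = 10**intercept``.

    Parameters
    ----------
    prices, consumptions : sequences of positive floats, length >= 3.
    """

    def __init__(self, prices: Sequence[float], consumptions: Sequence[float]):
        p = np.asarray(prices, dtype=float)
        q = np.asarray(consumptions, dtype=float)
        if p.size != q.size:
            raise ValueError("prices and consumptions must have equal length")
        if p.size < 3:
            raise ValueError("at least 3 points are required to fit a demand curve")
        if (p <= 0).any() or (q <= 0).any():
            raise ValueError("prices and consumptions must be positive")
        self.prices = p
        self.consumptions = q

    def fit(self) -> "DemandResults":
        X = sm.add_constant(np.log10(self.prices))
        ols = sm.OLS(np.log10(self.consumptions), X).fit()
        return DemandResults(model=self, _ols=ols)


@dataclass
class DemandResults:
    model: DemandModel
    _ols: object

    @property
    def epsilon(self) -> float:
        """Elasticity of demand (slope in log-log space)."""
        return float(self._ols.params[1])

    @property
    def A(self) -> float:
        """Scale constant, 10**intercept."""
        return float(10.0 ** self._ols.params[0])

    @property
    def epsilon_se(self) -> float:
        return float(self._ols.bse[1])

    @property
    def r_squared(self) -> float:
        return float(self._ols.rsquared)

    @property
    def n_points(self) -> int:
        return int(self.model.prices.size)

    def predict(self, prices) -> np.ndarray:
        p = np.asarray(prices, dtype=float)
        return self.A * p**self.epsilon

    def conf_int_epsilon(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = np.asarray(self._ols.conf_int(alpha))[1]
        return float(lo), float(hi)

    def summary(self) -> str:
        lo, hi = self.conf_int_epsilon()
        return (
            "Constant-elasticity demand fit  q = A * p**epsilon\n"
            f"  n points   : {self.n_points}\n"
            f"  epsilon    : {self.epsilon:.4g}  (SE {self.epsilon_se:.3g}, "
            f"95% CI [{lo:.4g}, {hi:.4g}])\n"
            f"  A          : {self.A:.4g}\n"
            f"  R^2 (logs) : {self.r_squared:.4f}"
        )

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "epsilon": self.epsilon,
            "epsilon_se": self.epsilon_se,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def fit_demand(prices, consumptions) -> DemandResults:
    """Convenience wrapper: ``DemandModel(prices, consumptions).fit()``."""
    return DemandModel(prices, consumptions).fit()


class PriceRatioSigmoidModel:
    """Exponential-sigmoid model of preference versus log price ratio.

    Nonlinear least squares over (r0, k) with k constrained positive.  When
    per-point sample sizes ``weights`` are given the residuals are weighted
    by sqrt(n) (inverse-variance surrogate for means of equally noisy
    worms); unweighted otherwise.
    """

    K_BOUNDS = (1e-3, 100.0)

    def __init__(
        self,
        r: Sequence[float],
        f_H: Sequence[float],
        weights: Optional[Sequence[float]] = None,
    ):
        r = np.asarray(r, dtype=float)
        f = np.asarray(f_H, dtype=float)
        if r.size != f.size:
            raise ValueError("r and f_H must have equal length")
        if np.unique(r).size < 3:
            raise ValueError("at least 3 distinct r values are required")
        if ((f < 0) | (f > 1)).any():
            raise ValueError("f_H values must lie in [0, 1]")
        if np.allclose(f, f[0]):
            raise ValueError("degenerate fit: all f_H values identical")
        self.r = r
        self.f_H = f
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            if w.size != r.size or (w <= 0).any():
                raise ValueError("weights must be positive and match r in length")
            self.weights = w
        else:
            self.weights = None

    def _start(self) -> tuple[float, float]:
        # r0 starts at the r whose f_H is nearest 0.5; k at half the r range.
        r0 = float(self.r[np.argmin(np.abs(self.f_H - 0.5))])
        k = max(0.5 * (self.r.max() - self.r.min()), 2 * self.K_BOUNDS[0])
        return r0, k

    def fit(self) -> "SigmoidResults":
        sqw = np.sqrt(self.weights) if self.weights is not None else 1.0

        def residuals(theta):
            r0, k = theta
            return sqw * (sigmoid(self.r, r0, k) - self.f_H)

        r0_0, k_0 = self._start()
        span = self.r.max() - self.r.min()
        sol = optimize.least_squares(
            residuals,
            x0=[r0_0, k_0],
            bounds=([self.r.min() - 10 * span - 1, self.K_BOUNDS[0]],
                    [self.r.max() + 10 * span + 1, self.K_BOUNDS[1]]),
        )
        if not sol.success:
            raise RuntimeError(f"sigmoid fit failed to converge: {sol.message}")
        rss = float(np.sum((sigmoid(self.r, *sol.x) - self.f_H) ** 2))
        return SigmoidResults(
            model=self, r0=float(sol.x[0]), k=float(sol.x[1]), rss=rss
        )


@dataclass
class SigmoidResults:
    """Fitted price-ratio sigmoid.

    The exchange weight ``w`` (units of M food per unit of H food near
    indifference) is exposed in two readings: ``w = 1 / r0`` as printed in
    the source analyses, and ``w_linear = 10**(-r0)``, the linear density
    ratio at indifference.  The former is undefined at r0 = 0.
    """

    model: Optional[PriceRatioSigmoidModel]
    r0: float
    k: float
    rss: float

    @property
    def w(self) -> float:
        """Exchange weight 1/r0 (reciprocal of the log ratio at indifference)."""
        if self.r0 == 0:
            raise ZeroDivisionError("w = 1/r0 is undefined at r0 = 0")
        return 1.0 / self.r0

    @property
    def w_linear(self) -> float:
        """Alternative reading: linear density ratio at indifference, 10**(-r0)."""
        return 10.0 ** (-self.r0)

    def __call__(self, r):
        return sigmoid(r, self.r0, self.k)

    predict = __call__

    def summary(self) -> str:
        return (
            "Price-ratio sigmoid fit  f_H(r) = 1/(1 + 10**(-(r - r0)/k))\n"
            f"  r0 (indifference) : {self.r0:.4g}\n"
            f"  k  (dynamic range): {self.k:.4g}\n"
            f"  RSS               : {self.rss:.4g}"
        )

    def to_dict(self) -> dict:
        return {"r0": self.r0, "k": self.k, "rss": self.rss}


def fit_price_ratio_sigmoid(r, f_H, weights=None) -> SigmoidResults:
    """Convenience wrapper: ``PriceRatioSigmoidModel(r, f_H, weights).fit()``."""
    return PriceRatioSigmoidModel(r, f_H, weights).fit()


class PiecewiseLinearCurve:
    """Piecewise-linear price-ratio curve through ordered (r, f_H) knots.

    Evaluation clamps to the end values outside the knot range so that f_H
    stays in [0, 1] on ensembles spanning ratios beyond the fitted points.
    """

    def __init__(self, knots: Sequence[tuple[float, float]]):
        pts = sorted((float(r), float(f)) for r, f in knots)
        r = np.array([p[0] for p in pts])
        f = np.array([p[1] for p in pts])
        if r.size < 2:
            raise ValueError("at least two knots are required")
        if (np.diff(r) <= 0).any():
            raise ValueError("knot r values must be strictly increasing")
        if ((f < 0) | (f > 1)).any():
            raise ValueError("knot f_H values must lie in [0, 1]")
        self.knot_r = r
        self.knot_f = f

    @classmethod
    def from_summary(cls, r, mean_f_H) -> "PiecewiseLinearCurve":
        return cls(list(zip(r, mean_f_H)))

    @property
    def knots(self) -> list[tuple[float, float]]:
        return list(zip(self.knot_r.tolist(), self.knot_f.tolist()))

    @property
    def is_monotone(self) -> bool:
        return bool((np.diff(self.knot_f) >= 0).all())

    def __call__(self, r):
        # np.interp clamps to end values outside the knot range.
        out = np.interp(np.asarray(r, dtype=float), self.knot_r, self.knot_f)
        return out if out.ndim else float(out)

    predict = __call__


@dataclass(frozen=True)
class SlopeEstimate:
    slope: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "se": self.se,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "n_points": self.n_points,
        }


def substitutes_slope(prices_varying, consumption_constant_good) -> SlopeEstimate:
    """OLS slope of one good's consumption on the *other* good's price.

    A positive significant slope indicates the goods act as substitutes:
    when the alternative gets more expensive, consumption of the
    constant-price good rises.  Applied to triplets of budgets in which one
    food's price was held constant.
    """
    p = np.asarray(prices_varying, dtype=float)
    q = np.asarray(consumption_constant_good, dtype=float)
    if p.size != q.size:
        raise ValueError("inputs must have equal length")
    if p.size < 3:
        raise ValueError("at least 3 points are required")
    ols = sm.OLS(q, sm.add_constant(p)).fit()
    lo, hi = np.asarray(ols.conf_int(0.05))[1]
    return SlopeEstimate(
        slope=float(ols.params[1]),
        se=float(ols.bse[1]),
        ci95=(float(lo), float(hi)),
        p_value=float(ols.pvalues[1]),
        n_points=int(p.size),
    )
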