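"""Elementary economic quantities of the worm food-choice assay.

In the single-worm assay a semi-restrained *C. elegans* is offered two
bacterial suspensions -- a high-quality food H and a medium-quality food M --
and every pharyngeal pump is logged to one side or the other.  A pump is the
unit of expenditure ("muscular money"), so the price of a food is the number
of pumps needed to ingest one cell-scale unit of it:

    P_X = 1 / d_X        (pumps per cell-scale unit)

where ``d_X`` is the bacterial density in OD units and the pump volume is the
unit of volume.  Consumption is expressed proportionally,

    q_X = (n_X / N) * d_X,

with ``n_X`` the pumps spent in food X and ``N`` the total.  Under this
normalization each worm's expenditure satisfies the budget identity
``P_H q_H + P_M q_M = 1`` exactly, and the pump share ``f_H = n_H / N``
coincides with the expenditure share ``P_H q_H``.  These identities are the
bridge from raw pump counts to the (price vector, chosen bundle) pairs that
revealed-preference analysis consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BudgetSpec",
    "ChoiceObservation",
    "Bundle",
    "PreferenceIndexRecord",
    "ValueQuantities",
    "price",
    "proportional_consumption",
    "pump_share",
    "accumulation_index",
    "frequency_index",
    "dwell_time_index",
    "combined_preference",
    "food_values",
    "BUDGET_IDENTITY_RTOL",
]

#: Relative tolerance for the budget identity P_H q_H + P_M q_M = 1.  The
#: identity is pure arithmetic, so a tight tolerance catches mapping bugs.
BUDGET_IDENTITY_RTOL = 1e-9


class MissingFieldError(ValueError):
    """An optional field (dwell time, pump frequency) is absent but required."""


def price(d: float) -> float:
    """Price of a food, in pumps per cell-scale unit: ``P = 1/d``.

    Doubling bacterial density halves the energetic cost of consumption.

    Parameters
    ----------
    d : float
        Bacterial density in OD units; must be positive.
    """
    if not d > 0:
        raise ValueError(f"density must be positive, got {d!r}")
    return 1.0 / d


def proportional_consumption(n_X: float, N: float, d_X: float) -> float:
    """Proportional consumption ``q_X = (n_X / N) * d_X``.

    ``n_X`` is the number of pumps spent in food X, ``N`` the worm's total
    pump count, and ``d_X`` the food's density.  Together with :func:`price`
    this makes each worm's choice satisfy ``P_H q_H + P_M q_M = 1``.
    """
    if N <= 0:
        raise ValueError("total pump count N must be positive")
    if n_X < 0 or n_X > N:
        raise ValueError(f"pump count must satisfy 0 <= n_X <= N, got {n_X} of {N}")
    if d_X <= 0:
        raise ValueError("density must be positive")
    return (n_X / N) * d_X


def _share(a: float, b: float, what: str) -> float:
    if a < 0 or b < 0:
        raise ValueError(f"{what} must be non-negative")
    total = a + b
    if total <= 0:
        raise ValueError(f"at least one {what} must be positive")
    return a / total


def pump_share(n_H: float, n_M: float) -> float:
    """Fraction of pumps spent in H food, ``f_H = n_H / (n_H + n_M)``.

    0.5 is indifference between the two foods.
    """
    return _share(n_H, n_M, "pump count")


def accumulation_index(N_H: float, N_M: float) -> float:
    """Accumulation-assay preference index ``I = (N_H - N_M)/(N_H + N_M)``.

    ``N_H`` and ``N_M`` are worm counts on the two patches; +1 is absolute
    preference for H, -1 for M, 0 indifference.
    """
    if N_H < 0 or N_M < 0:
        raise ValueError("worm counts must be non-negative")
    if N_H + N_M <= 0:
        raise ValueError("at least one patch count must be positive")
    return (N_H - N_M) / (N_H + N_M)


def frequency_index(F_H: float, F_M: float) -> float:
    """Pumping-rate preference index ``F_H / (F_H + F_M)`` (pumping-rate model)."""
    return _share(F_H, F_M, "pump frequency")


def dwell_time_index(t_H: float, t_M: float) -> float:
    """Dwell-time preference index ``t_H / (t_H + t_M)`` (dwell-time model)."""
    return _share(t_H, t_M, "dwell time")


def combined_preference(F_H: float, t_H: float, F_M: float, t_M: float) -> float:
    """Preference from frequencies and dwell times, ``F_H t_H / (F_H t_H + F_M t_M)``.

    Because ``n_X = F_X * t_X``, this equals :func:`pump_share`.  It reduces to
    :func:`frequency_index` when dwell times are equal and to
    :func:`dwell_time_index` when frequencies are equal.
    """
    for v, name in ((F_H, "F_H"), (t_H, "t_H"), (F_M, "F_M"), (t_M, "t_M")):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return _share(F_H * t_H, F_M * t_M, "frequency-time product")


@dataclass(frozen=True)
class BudgetSpec:
    """One budget line: a pair of food densities and the prices they imply.

    In proportional-consumption space the budget line runs from the
    x-intercept ``(d_H, 0)`` (all pumps in H) to the y-intercept ``(0, d_M)``.
    ``r = log10(d_H / d_M)`` is the log price ratio ``log10(P_M / P_H)``,
    the abscissa of the price-ratio curve.
    """

    budget_id: str
    d_H: float
    d_M: float

    def __post_init__(self) -> None:
        if not (self.d_H > 0 and self.d_M > 0):
            raise ValueError(
                f"budget {self.budget_id!r}: densities must be positive "
                f"(d_H={self.d_H}, d_M={self.d_M})"
            )

    @property
    def p_H(self) -> float:
        return price(self.d_H)

    @property
    def p_M(self) -> float:
        return price(self.d_M)

    @property
    def r(self) -> float:
        """Log price ratio log10(P_M/P_H) = log10(d_H/d_M)."""
        return math.log10(self.d_H / self.d_M)

    @property
    def prices(self) -> np.ndarray:
        return np.array([self.p_H, self.p_M])

    @property
    def intercepts(self) -> tuple[float, float]:
        """(x, y) intercepts of the budget line in consumption space."""
        return (self.d_H, self.d_M)


@dataclass(frozen=True)
class ChoiceObservation:
    """One worm's choice on one budget line.

    Dwell times (and hence pump frequencies) are optional; operations that
    need them raise :class:`MissingFieldError` rather than imputing.
    """

    worm_id: str
    budget: BudgetSpec
    n_H: int
    n_M: int
    t_H: Optional[float] = None
    t_M: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_H < 0 or self.n_M < 0:
            raise ValueError("pump counts must be non-negative")
        for t, name in ((self.t_H, "t_H"), (self.t_M, "t_M")):
            if t is not None and t < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def N(self) -> int:
        """Total pumps."""
        return self.n_H + self.n_M

    @property
    def f_H(self) -> float:
        """Pump share in H food; equals the expenditure share P_H q_H."""
        return pump_share(self.n_H, self.n_M)

    @property
    def q_H(self) -> float:
        return proportional_consumption(self.n_H, self.N, self.budget.d_H)

    @property
    def q_M(self) -> float:
        return proportional_consumption(self.n_M, self.N, self.budget.d_M)

    @property
    def bundle(self) -> np.ndarray:
        return np.array([self.q_H, self.q_M])

    def _require_times(self) -> tuple[float, float]:
        if self.t_H is None or self.t_M is None:
            raise MissingFieldError(
                f"worm {self.worm_id!r}: dwell times are required but absent"
            )
        return self.t_H, self.t_M

    @property
    def F_H(self) -> float:
        """Mean pump frequency in H food, n_H / t_H (Hz)."""
        t_H, _ = self._require_times()
        if t_H <= 0:
            raise ValueError("t_H must be positive to define F_H")
        return self.n_H / t_H

    @property
    def F_M(self) -> float:
        _, t_M = self._require_times()
        if t_M <= 0:
            raise ValueError("t_M must be positive to define F_M")
        return self.n_M / t_M

    def check_budget_identity(self) -> None:
        """Assert P_H q_H + P_M q_M = 1 to relative tolerance."""
        lhs = self.budget.p_H * self.q_H + self.budget.p_M * self.q_M
        if not math.isclose(lhs, 1.0, rel_tol=BUDGET_IDENTITY_RTOL):
            raise AssertionError(f"budget identity violated: {lhs!r} != 1")


@dataclass(frozen=True)
class Bundle:
    """A priced bundle of goods (general n-good form)."""

    quantities: tuple
    prices: tuple

    def __post_init__(self) -> None:
        q = np.asarray(self.quantities, dtype=float)
        p = np.asarray(self.prices, dtype=float)
        if q.shape != p.shape or q.ndim != 1 or q.size < 2:
            raise ValueError("quantities and prices must be equal-length vectors (>= 2)")
        if (q < 0).any():
            raise ValueError("quantities must be non-negative")
        if (p <= 0).any():
            raise ValueError("prices must be positive")

    @property
    def expenditure(self) -> float:
        return float(
            np.dot(np.asarray(self.quantities, float), np.asarray(self.prices, float))
        )


@dataclass(frozen=True)
class PreferenceIndexRecord:
    """Worm counts on two patches and the preference index they imply."""

    N_H: int
    N_M: int

    @property
    def I(self) -> float:  # noqa: E743 - the field name used in the assay
        return accumulation_index(self.N_H, self.N_M)


@dataclass(frozen=True)
class ValueQuantities:
    """Food values on the M-food scale: V_M = d_M and V_H = w * d_H.

    ``w`` is the exchange weight -- units of M food equivalent to one unit of
    H food near the indifference point of the price-ratio curve.
    """

    V_H: float
    V_M: float
    w: float


def food_values(d_H: float, d_M: float, w: float) -> ValueQuantities:
    """Food values referenced to M food: ``V_M = d_M``, ``V_H = w * d_H``."""
    if d_H <= 0 or d_M <= 0:
        raise ValueError("densities must be positive")
    if w <= 0:
        raise ValueError("exchange weight w must be positive")
    return ValueQuantities(V_H=w * d_H, V_M=d_M, w=w)
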