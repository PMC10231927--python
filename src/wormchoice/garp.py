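"""GARP engine: revealed-preference relations, violations, and the CCEI.

Given K budgets with price vectors ``p_i`` and chosen bundles ``x_i``, bundle
``x_i`` is *directly revealed weakly preferred* to ``x_j`` (``R0[i, j]``)
when ``x_j`` was affordable at budget i's prices, i.e. ``p_i . x_i >=
p_i . x_j``; it is *directly revealed strictly preferred* (``P0[i, j]``) when
``x_j`` cost strictly less.  ``R`` is the reflexive-transitive closure of
``R0``.  The Generalized Axiom of Revealed Preference requires that no pair
satisfies both ``R[i, j]`` and ``P0[j, i]``; such a pair is a *violation*,
classified direct when the offending preference ``R0[i, j]`` holds without
resort to transitivity, indirect otherwise.  GARP adherence is necessary and
sufficient for the choices to be consistent with maximization of a
non-satiated utility function.

Severity of violations is scored by Afriat's critical cost efficiency index
(CCEI): the largest uniform budget deflation ``e`` in [0, 1] under which the
deflated relations (``e * p_i . x_i >= p_i . x_j``) are violation-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import BudgetSpec

__all__ = [
    "PriceQuantityDataset",
    "RelationMatrices",
    "Violation",
    "GARPReport",
    "build_relations",
    "check_garp",
    "ccei",
    "verify_two_good_rose_property",
    "monotone_curve_implies_garp",
    "DEFAULT_EXPENDITURE_RTOL",
]

#: Relative tolerance on expenditures for weak/strict classification.  Mean
#: choices are ratios of counts, so exact ties are possible and must classify
#: as weak, not strict.
DEFAULT_EXPENDITURE_RTOL = 1e-8


@dataclass(frozen=True)
class PriceQuantityDataset:
    """K (price vector, chosen bundle) pairs -- the GARP input."""

    prices: np.ndarray
    bundles: np.ndarray
    budget_ids: Optional[tuple] = None

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.prices, dtype=float))
        x = np.atleast_2d(np.asarray(self.bundles, dtype=float))
        if p.shape != x.shape:
            raise ValueError(f"prices {p.shape} and bundles {x.shape} must match")
        if p.shape[0] == 0:
            raise ValueError("dataset must contain at least one budget")
        if (p <= 0).any():
            raise ValueError("all prices must be positive")
        if (x < 0).any():
            raise ValueError("all quantities must be non-negative")
        object.__setattr__(self, "prices", p)
        object.__setattr__(self, "bundles", x)
        if self.budget_ids is not None and len(self.budget_ids) != p.shape[0]:
            raise ValueError("budget_ids length must equal number of budgets")

    @property
    def K(self) -> int:
        return self.prices.shape[0]

    @property
    def n_goods(self) -> int:
        return self.prices.shape[1]

    @property
    def expenditures(self) -> np.ndarray:
        """Own expenditure p_i . x_i of each budget."""
        return np.einsum("ij,ij->i", self.prices, self.bundles)

    def cross_costs(self) -> np.ndarray:
        """Matrix C with C[i, j] = p_i . x_j (cost of bundle j at prices i)."""
        return self.prices @ self.bundles.T

    @classmethod
    def from_mean_shares(
        cls, ensemble: Sequence[BudgetSpec], shares: Sequence[float]
    ) -> "PriceQuantityDataset":
        """Build the GARP input from per-budget mean pump shares f_H.

        The bundle chosen on budget i is ``(f_H * d_H, (1 - f_H) * d_M)`` at
        prices ``(1/d_H, 1/d_M)``; every bundle then lies exactly on its
        budget line.
        """
        shares = np.asarray(shares, dtype=float)
        if len(ensemble) != shares.size:
            raise ValueError("one share per budget required")
        if ((shares < 0) | (shares > 1)).any():
            raise ValueError("shares must lie in [0, 1]")
        prices = np.array([[b.p_H, b.p_M] for b in ensemble])
        bundles = np.array(
            [[f * b.d_H, (1.0 - f) * b.d_M] for f, b in zip(shares, ensemble)]
        )
        return cls(prices, bundles, budget_ids=tuple(b.budget_id for b in ensemble))


@dataclass(frozen=True)
class RelationMatrices:
    """Boolean revealed-preference relations.

    ``R0`` weak direct, ``P0`` strict direct, ``R`` the reflexive-transitive
    closure of ``R0``.  Invariants: ``P0 <= R0 <= R`` elementwise, diagonal of
    ``R0`` true, ``R`` idempotent under further closure.
    """

    R0: np.ndarray
    P0: np.ndarray
    R: np.ndarray


def _transitive_closure(M: np.ndarray) -> np.ndarray:
    """Reflexive-transitive closure by repeated boolean squaring (K is small)."""
    R = M | np.eye(M.shape[0], dtype=bool)
    while True:
        R2 = R | (R @ R)
        if np.array_equal(R2, R):
            return R2
        R = R2


def build_relations(
    data: PriceQuantityDataset, tol: float = DEFAULT_EXPENDITURE_RTOL
) -> RelationMatrices:
    """Build R0, P0 and the transitive closure R from a dataset.

    ``tol`` is a relative tolerance on own expenditure: bundle j is weakly
    affordable at budget i when ``p_i.x_j <= p_i.x_i + tol * p_i.x_i`` and
    strictly cheaper when ``p_i.x_j < p_i.x_i - tol * p_i.x_i``.
    """
    e = data.expenditures
    C = data.cross_costs()
    slack = tol * e[:, None]
    R0 = e[:, None] >= C - slack
    P0 = e[:, None] > C + slack
    return RelationMatrices(R0=R0, P0=P0, R=_transitive_closure(R0))


@dataclass(frozen=True)
class Violation:
    """An ordered budget pair (i, j) with x_i revealed preferred to x_j and
    x_j strictly directly preferred to x_i."""

    i: int
    j: int
    kind: str  # "direct" | "indirect"


@dataclass(frozen=True)
class GARPReport:
    """Outcome of a GARP check with severity score."""

    passes: bool
    violations: tuple
    ccei: float
    relations: RelationMatrices
    monotone_curve: Optional[bool] = None  # set by monotone_curve_implies_garp

    @property
    def n_direct(self) -> int:
        return sum(1 for v in self.violations if v.kind == "direct")

    @property
    def n_indirect(self) -> int:
        return sum(1 for v in self.violations if v.kind == "indirect")

    def violation_cycles(self) -> list:
        """Aggregate ordered violation pairs to unordered cycles {i, j}."""
        return sorted({frozenset((v.i, v.j)) for v in self.violations}, key=sorted)

    def to_dict(self) -> dict:
        return {
            "passes": self.passes,
            "n_direct": self.n_direct,
            "n_indirect": self.n_indirect,
            "ccei": self.ccei,
            "violations": [
                {"i": v.i, "j": v.j, "kind": v.kind} for v in self.violations
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _find_violations(rel: RelationMatrices) -> tuple:
    out = []
    K = rel.R.shape[0]
    for i in range(K):
        for j in range(K):
            if i != j and rel.R[i, j] and rel.P0[j, i]:
                out.append(
                    Violation(i=i, j=j, kind="direct" if rel.R0[i, j] else "indirect")
                )
    return tuple(out)


def check_garp(
    data: PriceQuantityDataset,
    tol: float = DEFAULT_EXPENDITURE_RTOL,
    compute_ccei: bool = True,
) -> GARPReport:
    """Test a dataset for GARP violations and score their severity.

    A violation is an ordered pair (i, j) with ``R[i, j]`` and ``P0[j, i]``;
    it is direct when ``R0[i, j]`` already holds.  ``passes`` is true iff no
    violations exist, in which case the CCEI is 1.
    """
    rel = build_relations(data, tol=tol)
    violations = _find_violations(rel)
    passes = len(violations) == 0
    if compute_ccei:
        efficiency = 1.0 if passes else ccei(data)
    else:
        efficiency = float("nan")
    return GARPReport(
        passes=passes, violations=violations, ccei=efficiency, relations=rel
    )


def _passes_at(data: PriceQuantityDataset, e: float) -> bool:
    """GARP adherence with budgets uniformly deflated by e (exact comparisons)."""
    exp = data.expenditures * e
    C = data.cross_costs()
    R0 = exp[:, None] >= C
    P0 = exp[:, None] > C
    R = _transitive_closure(R0)
    np.fill_diagonal(R, False)  # self-pairs are never violations
    return not (R & P0.T).any()


def ccei(data: PriceQuantityDataset, bisect_tol: float = 1e-6) -> float:
    """Afriat's critical cost efficiency index, by bisection on [0, 1].

    Largest ``e`` such that relations built with ``e * p_i.x_i >= p_i.x_j``
    yield no violations.  1.0 means fully consistent.
    """
    if _passes_at(data, 1.0):
        return 1.0
    lo, hi = 0.0, 1.0  # lo passes (vacuously at 0), hi fails
    while hi - lo > bisect_tol:
        mid = 0.5 * (lo + hi)
        if _passes_at(data, mid):
            lo = mid
        else:
            hi = mid
    return lo


def verify_two_good_rose_property(
    data: PriceQuantityDataset, tol: float = DEFAULT_EXPENDITURE_RTOL
) -> bool:
    """For two goods, indirect violations require direct ones (Rose's theorem).

    Returns True iff the dataset is consistent with the theorem; intended as
    a randomized test oracle and expected to be always true.
    """
    if data.n_goods != 2:
        raise ValueError("the Rose property applies only to two-good datasets")
    report = check_garp(data, tol=tol, compute_ccei=False)
    if report.n_indirect > 0:
        return report.n_direct > 0
    return True


def monotone_curve_implies_garp(
    curve: Callable[[float], float],
    ensemble: Sequence[BudgetSpec],
    tol: float = DEFAULT_EXPENDITURE_RTOL,
    monotonicity_grid: int = 201,
) -> GARPReport:
    """Check that deterministic choices from a price-ratio curve satisfy GARP.

    A non-decreasing price-ratio curve f_H(r) precludes direct violations on
    any budget ensemble, and for two goods indirect violations require direct
    ones, so such choices always satisfy GARP.  The curve is evaluated at
    each budget's log price ratio, mapped to bundles on the budget lines, and
    the dataset is run through :func:`check_garp`.

    If the curve is found non-monotone on a grid spanning the ensemble's
    ratios the theorem does not apply; the check still runs and the report's
    ``monotone_curve`` flag is set False.
    """
    ratios = np.array([b.r for b in ensemble])
    shares = np.clip([float(curve(r)) for r in ratios], 0.0, 1.0)
    grid = np.linspace(ratios.min(), ratios.max(), monotonicity_grid)
    vals = np.array([float(curve(r)) for r in grid])
    monotone = bool((np.diff(vals) >= -1e-12).all())
    data = PriceQuantityDataset.from_mean_shares(ensemble, shares)
    report = check_garp(data, tol=tol)
    return GARPReport(
        passes=report.passes,
        violations=report.violations,
        ccei=report.ccei,
        relations=report.relations,
        monotone_curve=monotone,
    )
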