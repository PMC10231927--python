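"""Synthetic worm-choice data with the statistical structure the analysis assumes.

The generator stands in for the single-worm assay recordings: per budget
line, each simulated worm's mean preference follows the exponential sigmoid
price-ratio curve, its observed pump share adds bounded noise around that
mean, its total pump count is drawn from a count distribution, and (optional)
dwell times are allocated so that the dwell-time mechanism holds exactly --
equal pumping frequency on both sides, preference expressed purely through
time spent per side.  A CES variant generates exactly the data-generating
process assumed by the two-limit tobit.  Tables use the long-format
choice-table CSV layout, so every pipeline stage is testable without any
recorded data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BudgetSpec
from .curves import sigmoid
from .utility import CESParams, ces_optimal_share

__all__ = [
    "GeneratorSpec",
    "generate_ensemble",
    "simulate_choices",
    "simulate_ces_chooser",
    "write_fixtures",
    "DEFAULT_RATIOS",
    "default_worm_ensemble",
]

#: Log price ratios of the default seven-budget worm-style ensemble (geometric
#: anchoring at OD 1).  Spacing mirrors a worm assay: two budgets with very
#: dilute H food near the y-axis, one equal-density budget at r = 0.
DEFAULT_RATIOS = (-1.48, -1.0, -0.52, -0.48, 0.0, 0.48, 0.52)

#: Mean of the default total-pump-count distribution.  An arbitrary fixture
#: constant (assay totals are variable and no distribution is reported);
#: large enough that integer rounding barely perturbs the share.
DEFAULT_PUMP_MEAN = 1000.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Full parameterization of a synthetic choice experiment.

    ``r0``/``k`` are the ground-truth sigmoid parameters; ``noise_model`` is
    ``"truncated-normal"`` (dispersion = sd of the share before truncation)
    or ``"beta"`` (dispersion = sd scale of a mean-parameterized beta, for
    boundary-heavy data); ``pumps_model`` is ``"negative-binomial"``
    (dispersion parameter ``pumps_shape``) or ``"constant"``.
    """

    ensemble: tuple
    r0: float = -0.3
    k: float = 0.5
    noise_model: str = "truncated-normal"
    dispersion: float = 0.1
    pumps_model: str = "negative-binomial"
    pumps_mean: float = DEFAULT_PUMP_MEAN
    pumps_shape: float = 10.0
    n_worms_per_budget: int = 15
    with_dwell_times: bool = False
    pump_rate_hz: float = 4.0
    seed: Optional[int] = None
    group: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.ensemble) == 0:
            raise ValueError("ensemble must be non-empty")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_worms_per_budget < 1:
            raise ValueError("n_worms_per_budget must be >= 1")
        if self.pumps_model not in ("negative-binomial", "constant"):
            raise ValueError(f"unknown pumps_model {self.pumps_model!r}")
        if self.noise_model not in ("truncated-normal", "beta"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.pumps_mean <= 0 or self.pumps_shape <= 0 or self.pump_rate_hz <= 0:
            raise ValueError("pumps_mean, pumps_shape and pump_rate_hz must be positive")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "ensemble"}
        d["ensemble"] = [
            {"budget_id": b.budget_id, "d_H": b.d_H, "d_M": b.d_M}
            for b in self.ensemble
        ]
        return d


def generate_ensemble(
    ratios: Sequence[float],
    anchor_density: float = 1.0,
    prefix: str = "b",
) -> list[BudgetSpec]:
    """Budget lines with given log price ratios, anchored at a geometric mean.

    For each ratio r the densities satisfy ``d_H * d_M = anchor_density**2``
    and ``log10(d_H / d_M) = r``, i.e. ``d_H = anchor * 10**(r/2)`` and
    ``d_M = anchor * 10**(-r/2)``.  At r = 0 both foods sit at the anchor
    density (the equal-density budget of the assay).
    """
    if anchor_density <= 0:
        raise ValueError("anchor_density must be positive")
    ratios = np.asarray(ratios, dtype=float)
    if not np.isfinite(ratios).all():
        raise ValueError("ratios must be finite")
    return [
        BudgetSpec(
            budget_id=f"{prefix}{i}",
            d_H=anchor_density * 10.0 ** (r / 2.0),
            d_M=anchor_density * 10.0 ** (-r / 2.0),
        )
        for i, r in enumerate(ratios)
    ]


def default_worm_ensemble() -> list[BudgetSpec]:
    """The package's default seven-budget worm-style ensemble."""
    return generate_ensemble(DEFAULT_RATIOS)


def _draw_shares(
    rng: np.random.Generator, means: np.ndarray, spec: GeneratorSpec
) -> np.ndarray:
    if spec.dispersion == 0:
        return means.copy()
    if spec.noise_model == "truncated-normal":
        sd = spec.dispersion
        a, b = (0.0 - means) / sd, (1.0 - means) / sd
        return stats.truncnorm.rvs(
            a, b, loc=means, scale=sd, size=means.shape, random_state=rng
        )
    # beta: mean-parameterized with concentration chosen so the sd at
    # maximum-variance mean matches the dispersion parameter
    eps = 1e-6
    m = np.clip(means, eps, 1 - eps)
    conc = max(0.25 / spec.dispersion**2 - 1.0, 0.1)
    return rng.beta(m * conc, (1.0 - m) * conc)


def _draw_pumps(rng: np.random.Generator, n: int, spec: GeneratorSpec) -> np.ndarray:
    if spec.pumps_model == "constant":
        return np.full(n, int(round(spec.pumps_mean)))
    # negative binomial parameterized by mean and shape (size) parameter
    shape = spec.pumps_shape
    p = shape / (shape + spec.pumps_mean)
    draws = rng.negative_binomial(shape, p, size=n)
    return np.maximum(draws, 1)  # every worm pumps at least once


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(np.int64)


def _assemble_table(
    ensemble: Sequence[BudgetSpec],
    shares: np.ndarray,
    pumps: np.ndarray,
    spec_group: str,
    with_times: bool,
    pump_rate: float,
) -> pd.DataFrame:
    rows = []
    idx = 0
    n_per = shares.shape[1]
    for bi, budget in enumerate(ensemble):
        for wi in range(n_per):
            N = int(pumps[bi, wi])
            n_H = int(np.clip(_round_half_even(np.array(shares[bi, wi] * N)), 0, N))
            n_M = N - n_H
            row = {
                "group": spec_group,
                "budget_id": budget.budget_id,
                "d_H": budget.d_H,
                "d_M": budget.d_M,
                "worm_id": f"w{idx:05d}",
                "n_H": n_H,
                "n_M": n_M,
            }
            if with_times:
                # equal pumping frequency on both sides: preference is
                # expressed purely through dwell time (t_X = n_X / F)
                row["t_H"] = n_H / pump_rate
                row["t_M"] = n_M / pump_rate
            else:
                row["t_H"] = np.nan
                row["t_M"] = np.nan
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


def simulate_choices(spec: GeneratorSpec) -> pd.DataFrame:
    """Simulate a long-format choice table from a sigmoid price-ratio curve.

    Per worm: mean share m = sigmoid(r; r0, k); observed share drawn from
    the noise model with mean m; total pumps N from the pumps model;
    ``n_H = round(share * N)`` (round-half-to-even), ``n_M = N - n_H``.
    """
    rng = np.random.default_rng(spec.seed)
    ratios = np.array([b.r for b in spec.ensemble])
    means = np.asarray(sigmoid(ratios, spec.r0, spec.k))
    K, n = len(spec.ensemble), spec.n_worms_per_budget
    shares = _draw_shares(
        rng, np.repeat(means[:, None], n, axis=1).reshape(K, n), spec
    )
    pumps = _draw_pumps(rng, K * n, spec).reshape(K, n)
    return _assemble_table(
        spec.ensemble, shares, pumps, spec.group, spec.with_dwell_times,
        spec.pump_rate_hz,
    )


def simulate_ces_chooser(
    params: CESParams,
    sigma: float,
    ensemble: Sequence[BudgetSpec],
    n_worms: int,
    seed: Optional[int] = None,
    pumps_mean: float = DEFAULT_PUMP_MEAN,
    group: str = "ces-synthetic",
) -> pd.DataFrame:
    """Simulate choices of a noisy CES maximizer (the tobit's DGP).

    The latent share at each budget is the CES optimum plus Normal(0, sigma)
    noise *censored* (clipped) to [0, 1] -- exactly the two-limit tobit
    data-generating process -- then converted to pump counts.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    latent = np.array([ces_optimal_share(params, b.p_H, b.p_M) for b in ensemble])
    K = len(ensemble)
    shares = np.clip(
        latent[:, None] + rng.normal(0.0, sigma, size=(K, n_worms)), 0.0, 1.0
    )
    pumps = np.full((K, n_worms), int(round(pumps_mean)))
    return _assemble_table(ensemble, shares, pumps, group, False, 4.0)


def write_fixtures(
    tables: dict,
    directory: str,
    spec: Optional[GeneratorSpec] = None,
) -> list[str]:
    """Write choice tables as CSV plus a manifest JSON with full provenance.

    ``tables`` maps file stems to DataFrames in the choice-table layout.
    Returns the list of paths written.
    """
    os.makedirs(directory, exist_ok=True)
    paths = []
    for stem, table in tables.items():
        path = os.path.join(directory, f"{stem}.csv")
        table.to_csv(path, index=False)
        paths.append(path)
    manifest = {
        "generator": spec.to_dict() if spec is not None else None,
        "seed": spec.seed if spec is not None else None,
        "files": [os.path.basename(p) for p in paths],
        "version": 1,
    }
    mpath = os.path.join(directory, "manifest.json")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    paths.append(mpath)
    return paths
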