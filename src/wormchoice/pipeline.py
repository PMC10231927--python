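"""End-to-end analysis pipeline: choice table -> GARP report + fits + simulations.

``run_pipeline`` reproduces the full analysis chain for each group in a
choice table (e.g. trained and untrained worms): per-budget summaries, the
GARP check with CCEI on group-mean choices, constant-elasticity demand fits
for both foods, the price-ratio sigmoid fit, the CES two-limit tobit fit,
and the three Monte-Carlo robustness procedures.  Results are assembled into
a JSON-serializable report with full provenance (seeds, config digest,
package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import BudgetSpec
from .curves import fit_demand, fit_price_ratio_sigmoid, PiecewiseLinearCurve
from .garp import PriceQuantityDataset, check_garp, DEFAULT_EXPENDITURE_RTOL
from .io import (
    ParseError,
    ensemble_from_table,
    load_ensemble,
    read_choice_table,
    summarize_choices,
    write_summary_table,
)
from .simulate import (
    gaussian_resample_violation_probability,
    model_maximization_probability,
    random_chooser_false_positive,
)
from .utility import CESTobitModel

__all__ = ["AnalysisConfig", "run_pipeline", "REPORT_SCHEMA_PATH", "validate_report"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_PATH = os.path.join(os.path.dirname(__file__), "data", "report.schema.json")


@dataclass
class AnalysisConfig:
    """Settings for one pipeline run."""

    choices_path: str
    output_dir: str
    ensemble_path: Optional[str] = None  # defaults to the table's own budgets
    prediction_ensemble_path: Optional[str] = None  # e.g. an 11-budget config
    expenditure_rtol: float = DEFAULT_EXPENDITURE_RTOL
    n_sims: int = 10**5
    seed: int = 0
    groups: Optional[list] = None  # subset of groups; None = all in table

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Digest of the analysis-relevant settings (output location excluded)."""
        fields = {
            k: v for k, v in dataclasses.asdict(self).items() if k != "output_dir"
        }
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _analyze_group(
    group: str,
    table: pd.DataFrame,
    config: AnalysisConfig,
    prediction_ensemble,
) -> dict:
    summary = summarize_choices(table)
    ensemble = ensemble_from_table(summary)
    order = {b.budget_id: i for i, b in enumerate(ensemble)}
    summary = summary.sort_values(
        "budget_id", key=lambda s: s.map(order)
    ).reset_index(drop=True)

    # GARP on group-mean choices
    data = PriceQuantityDataset.from_mean_shares(ensemble, summary["mean_fH"])
    garp_report = check_garp(data, tol=config.expenditure_rtol)

    # demand fits: mean proportional consumption of each food vs its price
    shares = summary["mean_fH"].to_numpy()
    q_H = shares * summary["d_H"].to_numpy()
    q_M = (1 - shares) * summary["d_M"].to_numpy()
    p_H = 1.0 / summary["d_H"].to_numpy()
    p_M = 1.0 / summary["d_M"].to_numpy()
    demand = {}
    for food, (p, q) in {"H": (p_H, q_H), "M": (p_M, q_M)}.items():
        ok = q > 0
        try:
            demand[food] = fit_demand(p[ok], q[ok]).to_dict()
        except ValueError as exc:
            logger.warning("group %s: demand fit for %s skipped (%s)", group, food, exc)
            demand[food] = None

    # price-ratio sigmoid (weighted by per-budget n) and piecewise alternative
    sigmoid_fit = fit_price_ratio_sigmoid(
        summary["r"], summary["mean_fH"], weights=summary["n"]
    )
    piecewise = PiecewiseLinearCurve.from_summary(summary["r"], summary["mean_fH"])

    # CES two-limit tobit on per-worm shares
    tobit = CESTobitModel.from_dataframe(table).fit()

    # Monte-Carlo robustness
    group_tag = int.from_bytes(hashlib.sha256(group.encode()).digest()[:4], "big")
    seed = np.random.SeedSequence([config.seed, group_tag % 2**31])
    s1, s2, s3, s4 = [int(s.generate_state(1)[0] % 2**31) for s in seed.spawn(4)]
    sims = {
        "bronars_own_ensemble": random_chooser_false_positive(
            ensemble, n_sims=config.n_sims, seed=s1
        ).to_dict(),
        "gaussian_resample": gaussian_resample_violation_probability(
            summary["mean_fH"],
            summary["sem_fH"].fillna(0.0),
            ensemble,
            n_sims=config.n_sims,
            seed=s2,
        ).to_dict(),
    }
    max_sem = float(np.nanmax(summary["sem_fH"].to_numpy()))
    if prediction_ensemble is not None and np.isfinite(max_sem):
        sims["model_maximization_sigmoid"] = model_maximization_probability(
            sigmoid_fit, prediction_ensemble, max_sem,
            n_sims=config.n_sims, seed=s3,
        ).to_dict()
        sims["model_maximization_piecewise"] = model_maximization_probability(
            piecewise, prediction_ensemble, max_sem,
            n_sims=config.n_sims, seed=s4,
        ).to_dict()

    return {
        "summary": summary.drop(columns=["group"]).to_dict(orient="records"),
        "garp": garp_report.to_dict(),
        "demand": demand,
        "sigmoid": sigmoid_fit.to_dict(),
        "piecewise_knots": piecewise.knots,
        "ces_tobit": tobit.to_dict(),
        "simulations": sims,
        "_summary_frame": summary,
    }


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis and write report JSON + summary CSVs.

    Returns the report dict (also written to ``<output_dir>/report.json``).
    """
    table = read_choice_table(config.choices_path)
    if config.ensemble_path:
        declared = {b.budget_id: b for b in load_ensemble(config.ensemble_path)}
        for bid, sub in table.groupby("budget_id"):
            bid = str(bid)
            if bid not in declared:
                raise ParseError(
                    f"budget {bid!r} in table is absent from the ensemble config"
                )
            b = declared[bid]
            if not (
                np.allclose(sub["d_H"], b.d_H) and np.allclose(sub["d_M"], b.d_M)
            ):
                raise ParseError(
                    f"budget {bid!r}: densities in table disagree with ensemble config"
                )
    prediction_ensemble = (
        load_ensemble(config.prediction_ensemble_path)
        if config.prediction_ensemble_path
        else None
    )

    groups = config.groups or sorted(table["group"].astype(str).unique())
    os.makedirs(config.output_dir, exist_ok=True)
    report = {
        "provenance": {
            "version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_sims": config.n_sims,
            "choices_path": os.path.abspath(config.choices_path),
        },
        "groups": {},
    }
    for group in groups:
        sub = table[table["group"].astype(str) == group]
        if len(sub) == 0:
            raise ParseError(f"group {group!r} not present in the choice table")
        result = _analyze_group(group, sub, config, prediction_ensemble)
        summary = result.pop("_summary_frame")
        write_summary_table(
            summary.assign(group=group),
            os.path.join(config.output_dir, f"summary_{group}.csv"),
        )
        report["groups"][group] = result

    validate_report(report)
    with open(os.path.join(config.output_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report


def _check_schema(instance, schema, path="$") -> None:
    stype = schema.get("type")
    if stype == "object":
        if not isinstance(instance, dict):
            raise ValueError(f"{path}: expected object")
        for key in schema.get("required", []):
            if key not in instance:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check_schema(instance[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key in instance:
                if key not in schema.get("properties", {}):
                    _check_schema(instance[key], extra, f"{path}.{key}")
    elif stype == "array":
        if not isinstance(instance, list):
            raise ValueError(f"{path}: expected array")
        if "items" in schema:
            for i, item in enumerate(instance):
                _check_schema(item, schema["items"], f"{path}[{i}]")
    elif stype == "number":
        if not isinstance(instance, (int, float)) or isinstance(instance, bool):
            raise ValueError(f"{path}: expected number")
    elif stype == "integer":
        if not isinstance(instance, int) or isinstance(instance, bool):
            raise ValueError(f"{path}: expected integer")
    elif stype == "string":
        if not isinstance(instance, str):
            raise ValueError(f"{path}: expected string")
    elif stype == "boolean":
        if not isinstance(instance, bool):
            raise ValueError(f"{path}: expected boolean")


def validate_report(report: dict) -> None:
    """Validate a report dict against the shipped JSON schema (subset checker)."""
    with open(REPORT_SCHEMA_PATH, "r", encoding="utf-8") as fh:
        schema = json.load(fh)
    _check_schema(report, schema)
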