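"""Readers and writers for choice tables, summaries, and ensemble configs.

Two CSV layouts are used throughout (comma-separated, UTF-8, "." decimal,
header required, missing optional values as empty fields):

* *choice tables* -- one row per worm per budget:
  ``group, budget_id, d_H, d_M, worm_id, n_H, n_M, t_H, t_M``
  (the last two optional, empty allowed);
* *summary tables* -- one row per budget:
  ``group, budget_id, d_H, d_M, mean_fH, sem_fH, n``.

Budget-ensemble configs are JSON or YAML lists of either worm-style entries
``{budget_id, d_H, d_M}`` or human-style entries
``{budget_id, p_x, p_y, income}``; the latter are converted to intercept
form (``d = income / p``), which is the shared internal representation.
"""

from __future__ import annotations

import json
import math
import os
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import BudgetSpec

__all__ = [
    "ParseError",
    "read_choice_table",
    "write_choice_table",
    "read_summary_table",
    "write_summary_table",
    "summarize_choices",
    "ensemble_from_table",
    "load_ensemble",
    "dump_ensemble",
]

CHOICE_COLUMNS = ["group", "budget_id", "d_H", "d_M", "worm_id", "n_H", "n_M"]
OPTIONAL_COLUMNS = ["t_H", "t_M"]
SUMMARY_COLUMNS = ["group", "budget_id", "d_H", "d_M", "mean_fH", "sem_fH", "n"]


class ParseError(ValueError):
    """A malformed input file; the message names the offending row/column."""


def read_choice_table(path: str) -> pd.DataFrame:
    """Read and validate a long-format choice table CSV."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty input file") from exc
    missing = [c for c in CHOICE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    if len(table) == 0:
        raise ParseError(f"{path}: no data rows")
    for col in ("d_H", "d_M", "n_H", "n_M", "t_H", "t_M"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            row = int(table.index[bad][0])
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {row}")
        table[col] = vals
    if (table[["d_H", "d_M"]] <= 0).any().any():
        raise ParseError(f"{path}: densities must be positive")
    if (table[["n_H", "n_M"]] < 0).any().any():
        raise ParseError(f"{path}: pump counts must be non-negative")
    if ((table["n_H"] + table["n_M"]) <= 0).any():
        raise ParseError(f"{path}: every worm must have at least one pump")
    return table


def write_choice_table(table: pd.DataFrame, path: str) -> None:
    cols = CHOICE_COLUMNS + OPTIONAL_COLUMNS
    out = table.copy()
    for col in OPTIONAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[cols].to_csv(path, index=False)


def read_summary_table(path: str) -> pd.DataFrame:
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty input file") from exc
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return table


def write_summary_table(summary: pd.DataFrame, path: str) -> None:
    summary[SUMMARY_COLUMNS].to_csv(path, index=False)


def summarize_choices(table: pd.DataFrame) -> pd.DataFrame:
    """Per-budget summary of a choice table: mean f_H, SEM, and n.

    Budgets with a single worm get an undefined (NaN) SEM.  The summary is
    sorted by group and log price ratio.
    """
    t = table.copy()
    t["f_H"] = t["n_H"] / (t["n_H"] + t["n_M"])
    rows = []
    for (group, budget_id), sub in t.groupby(["group", "budget_id"], sort=False):
        n = len(sub)
        mean = float(sub["f_H"].mean())
        sem = float(sub["f_H"].std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "group": group,
                "budget_id": budget_id,
                "d_H": float(sub["d_H"].iloc[0]),
                "d_M": float(sub["d_M"].iloc[0]),
                "mean_fH": mean,
                "sem_fH": sem,
                "n": n,
            }
        )
    out = pd.DataFrame(rows)
    out["r"] = np.log10(out["d_H"] / out["d_M"])
    return out.sort_values(["group", "r"]).reset_index(drop=True)


def ensemble_from_table(table: pd.DataFrame, group: Optional[str] = None) -> list:
    """Budget ensemble implied by a choice or summary table (ordered by r)."""
    t = table if group is None else table[table["group"] == group]
    seen = {}
    for _, row in t.iterrows():
        bid = str(row["budget_id"])
        spec = BudgetSpec(budget_id=bid, d_H=float(row["d_H"]), d_M=float(row["d_M"]))
        if bid in seen:
            if not (
                math.isclose(seen[bid].d_H, spec.d_H)
                and math.isclose(seen[bid].d_M, spec.d_M)
            ):
                raise ParseError(
                    f"budget {bid!r}: inconsistent density definitions within table"
                )
        else:
            seen[bid] = spec
    return sorted(seen.values(), key=lambda b: b.r)


def _entry_to_budget(entry: dict, index: int) -> BudgetSpec:
    bid = str(entry.get("budget_id", f"b{index}"))
    if "d_H" in entry and "d_M" in entry:
        return BudgetSpec(budget_id=bid, d_H=float(entry["d_H"]), d_M=float(entry["d_M"]))
    if {"p_x", "p_y", "income"} <= set(entry):
        income = float(entry["income"])
        if income <= 0:
            raise ParseError(f"budget {bid!r}: income must be positive")
        return BudgetSpec(
            budget_id=bid,
            d_H=income / float(entry["p_x"]),
            d_M=income / float(entry["p_y"]),
        )
    raise ParseError(
        f"budget entry {index}: need either (d_H, d_M) or (p_x, p_y, income); "
        f"got keys {sorted(entry)}"
    )


def load_ensemble(path: str) -> list:
    """Load a budget ensemble from a JSON or YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        if path.endswith((".yaml", ".yml")):
            raw = yaml.safe_load(fh)
        else:
            raw = json.load(fh)
    if isinstance(raw, dict) and "budgets" in raw:
        raw = raw["budgets"]
    if not isinstance(raw, list) or not raw:
        raise ParseError(f"{path}: expected a non-empty list of budget entries")
    out = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict):
            raise ParseError(f"{path}: budget entry {i} is not a mapping")
        if any(v is None for v in entry.values()):
            raise ParseError(
                f"{path}: budget entry {i} has null fields -- populate the "
                "template with real values before use"
            )
        out.append(_entry_to_budget(entry, i))
    return out


def dump_ensemble(ensemble: Sequence[BudgetSpec], path: str) -> None:
    data = [
        {"budget_id": str(b.budget_id), "d_H": float(b.d_H), "d_M": float(b.d_M)}
        for b in ensemble
    ]
    with open(path, "w", encoding="utf-8") as fh:
        if path.endswith((".yaml", ".yml")):
            yaml.safe_dump(data, fh)
        else:
            json.dump(data, fh, indent=2)
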