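"""Reading and writing trial tables, fit results and configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult
from .params import DDMParams, LDCParams

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trials",
    "write_trials",
    "read_config",
    "fit_result_to_dict",
    "write_fit_result",
    "read_fit_result",
]

REQUIRED_COLUMNS = [
    "participant",
    "condition",
    "difficulty",
    "stim_sign",
    "choice",
    "accuracy",
    "decision_rt",
    "confidence_rt",
    "rating",
]

_OPTIONAL_COLUMNS = ["evidence_dec", "evidence_total", "acc_time", "confidence", "feedback"]


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the trial-table schema, naming the offending column/rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if len(table) == 0:
        raise ValueError("trial table is empty")
    rating = table["rating"]
    bad = ~rating.isin(range(1, 7))
    if bad.any():
        raise ValueError(
            f"column 'rating' must be in 1..6; offending rows: {list(table.index[bad][:5])}"
        )
    for col in ("decision_rt", "confidence_rt"):
        neg = table[col] < 0
        if neg.any():
            raise ValueError(
                f"column {col!r} must be >= 0; offending rows: {list(table.index[neg][:5])}"
            )
    for col, allowed in (("stim_sign", (-1, 1)), ("choice", (-1, 1)), ("accuracy", (0, 1))):
        bad = ~table[col].isin(allowed)
        if bad.any():
            raise ValueError(
                f"column {col!r} must be in {allowed}; offending rows: {list(table.index[bad][:5])}"
            )
    return table


def read_trials(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_trials(table)


def write_trials(table: pd.DataFrame, path) -> None:
    validate_trials(table)
    cols = REQUIRED_COLUMNS + [c for c in _OPTIONAL_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.8g")


def read_config(path) -> dict:
    """Load a YAML (or JSON — valid YAML) configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def _jsonable(obj):
    if isinstance(obj, (DDMParams, LDCParams)):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "variant": fit.variant,
        "ddm": dataclasses.asdict(fit.ddm),
        "ldc_by_condition": {
            c: dataclasses.asdict(p) for c, p in fit.ldc_by_condition.items()
        },
        "sse": fit.sse,
        "k": fit.k,
        "n": fit.n,
        "seed": fit.seed,
        "rt_sse": fit.rt_sse,
        "conf_sse": fit.conf_sse,
        "trace": [[int(g), float(v)] for g, v in fit.trace],
    }


def write_fit_result(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=1, default=_jsonable))


def read_fit_result(path) -> FitResult:
    d = json.loads(Path(path).read_text())
    return FitResult(
        ddm=DDMParams(**d["ddm"]),
        ldc_by_condition={c: LDCParams(**p) for c, p in d["ldc_by_condition"].items()},
        sse=d["sse"],
        k=d["k"],
        n=d["n"],
        seed=d["seed"],
        variant=d["variant"],
        trace=[tuple(t) for t in d.get("trace", [])],
        rt_sse=d.get("rt_sse"),
        conf_sse=d.get("conf_sse"),
    )
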