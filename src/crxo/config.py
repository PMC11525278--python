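"""Scenario configuration and report rendering.

A scenario is a flat key-value document (YAML file or plain dict).  Defaults
reproduce the package's reference scenario — a worksite sedentary-behaviour
trial with rho = 0.1, r = 0.95, 25 subjects per cluster-period, cluster /
subject / switch costs of 2500 / 25 / 250 and a budget of 250,000.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .designs import CostStructure
from .efficiency import DesignEvaluation, DesignSpaceRequest, evaluations_frame
from .exceptions import ConfigurationError, InvalidParameterError
from .variance import MAX_PERIODS, CorrelationParams

__all__ = ["ScenarioConfig", "load_config", "render_reports", "REPORT_COLUMNS"]

#: Stable column order for rendered reports.
REPORT_COLUMNS = ["label", "sequence", "T", "switches", "K", "cost", "var_theta",
                  "relative_efficiency"]

_COST_KEYS = ("c_c", "c_s", "c_x", "budget")


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated scenario: design space, model parameters and output options."""

    mode: str = "budget"
    scope: str = "alternating"
    periods: tuple[int, ...] = tuple(range(2, MAX_PERIODS + 1))
    sequence: str | None = None
    rho: float = 0.1
    r: float = 0.95
    total_variance: float = 1.0
    m: int = 25
    K: int | None = None
    c_c: float = 2500
    c_s: float = 25
    c_x: float = 250
    budget: float = 250_000
    max_periods: int = MAX_PERIODS
    seed: int = 20260101
    precision: int = 3
    output: str | None = None
    format: str = "csv"

    def params(self) -> CorrelationParams:
        return CorrelationParams(rho=self.rho, r=self.r, total_variance=self.total_variance)

    def costs(self) -> CostStructure:
        return CostStructure(c_c=self.c_c, c_s=self.c_s, c_x=self.c_x, budget=self.budget)

    def request(self) -> DesignSpaceRequest:
        """The design-space request this scenario describes."""
        return DesignSpaceRequest(
            mode=self.mode,
            periods=self.periods,
            scope=self.scope,
            params=self.params(),
            m=self.m,
            K=self.K if self.mode == "fixed_k" else None,
            costs=self.costs() if self.mode == "budget" else None,
            max_periods=self.max_periods,
        )


_FIELDS = {f.name: f for f in dataclasses.fields(ScenarioConfig)}


def _check_range(key: str, value) -> None:
    if key in ("rho", "r") and not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{key} must be in [0, 1], got {value}")
    if key == "total_variance" and value <= 0:
        raise ConfigurationError(f"total_variance must be positive, got {value}")
    if key == "m" and (not isinstance(value, int) or value < 1):
        raise ConfigurationError(f"m must be a positive integer, got {value}")
    if key == "K" and value is not None and (value < 2 or value % 2):
        raise ConfigurationError(f"K must be an even integer >= 2, got {value}")
    if key in ("c_c", "c_s", "c_x") and value < 0:
        raise ConfigurationError(f"{key} must be nonnegative, got {value}")
    if key == "budget" and value <= 0:
        raise ConfigurationError(f"budget must be positive, got {value}")
    if key == "precision" and (not isinstance(value, int) or value < 0):
        raise ConfigurationError(f"precision must be a nonnegative integer, got {value}")
    if key == "mode" and value not in ("budget", "fixed_k"):
        raise ConfigurationError(f"mode must be 'budget' or 'fixed_k', got {value!r}")
    if key == "scope" and value not in ("alternating", "all_pairs"):
        raise ConfigurationError(f"scope must be 'alternating' or 'all_pairs', got {value!r}")
    if key == "format" and value not in ("csv", "json"):
        raise ConfigurationError(f"format must be 'csv' or 'json', got {value!r}")


def load_config(document: "dict | str | Path | None" = None, **overrides) -> ScenarioConfig:
    """Build a validated :class:`ScenarioConfig` from a document plus overrides.

    ``document`` may be a dict, a YAML file path, or None.  Unknown keys and
    out-of-range values are rejected with the offending key named; supplying
    costs in ``fixed_k`` mode (or ``K`` in ``budget`` mode) is a conflict.
    """
    data: dict = {}
    if isinstance(document, (str, Path)):
        with open(document) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("configuration document must be a mapping")
        data.update(loaded)
    elif isinstance(document, dict):
        data.update(document)
    elif document is not None:
        raise ConfigurationError("configuration document must be a mapping or a path")
    data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - set(_FIELDS)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    if "periods" in data:
        try:
            data["periods"] = tuple(int(t) for t in data["periods"])
        except TypeError:
            data["periods"] = (int(data["periods"]),)
    for key, value in data.items():
        _check_range(key, value)

    mode = data.get("mode", ScenarioConfig.mode)
    if mode == "fixed_k":
        supplied_costs = [k for k in _COST_KEYS if k in data]
        if supplied_costs:
            raise ConfigurationError(
                f"fixed_k mode conflicts with cost keys: {supplied_costs}"
            )
        if "K" not in data:
            raise ConfigurationError("fixed_k mode requires K")
    elif "K" in data and data["K"] is not None:
        raise ConfigurationError("budget mode derives K from the budget; do not supply K")

    config = ScenarioConfig(**data)
    try:
        config.params()
    except InvalidParameterError as exc:
        raise ConfigurationError(str(exc)) from exc
    return config


def render_reports(
    evaluations: "list[DesignEvaluation] | pd.DataFrame",
    format: str = "csv",
    path: "str | Path | None" = None,
    precision: int = 3,
) -> str:
    """Render evaluations as CSV or JSON with a stable column order.

    Floating-point columns are rounded to ``precision`` decimals; the JSON
    output holds exactly the rendered numbers, so it round-trips losslessly.
    Returns the rendered text (and writes it to ``path`` when given).
    """
    if isinstance(evaluations, pd.DataFrame):
        frame = evaluations.copy()
    else:
        if not evaluations:
            raise InvalidParameterError("nothing to render")
        frame = evaluations_frame(evaluations)
    if frame.empty:
        raise InvalidParameterError("nothing to render")
    if "label" not in frame.columns:
        frame.insert(0, "label", range(1, len(frame) + 1))
    ordered = [c for c in REPORT_COLUMNS if c in frame.columns]
    ordered += [c for c in frame.columns if c not in ordered]
    frame = frame[ordered]
    for col in ("var_theta", "relative_efficiency", "re_fixed_k", "re_budget"):
        if col in frame.columns:
            frame[col] = frame[col].astype(float).round(precision)

    if format == "csv":
        text = frame.to_csv(index=False)
    elif format == "json":
        records = json.loads(frame.to_json(orient="records"))
        text = json.dumps(records, indent=2)
    else:
        raise ConfigurationError(f"format must be 'csv' or 'json', got {format!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
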