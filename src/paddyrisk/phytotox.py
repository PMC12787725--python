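"""Descriptive phytotoxicity endpoints: percent change vs. control.

Growth (plant height, root length, dry weights, tiller and panicle
counts), oxidative-stress markers (MDA, SOD, POD, CAT) and rhizosphere
amino-acid endpoints are summarised as the percent change of the
contaminated-group mean relative to the control-group mean, per endpoint,
growth stage and tissue.  Negative values are inhibition, positive values
stimulation.  Replicate spread is reported as the SD of per-replicate
percent changes against the control mean; formal significance testing is
deliberately left to external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .core_data import DataValidationError, Group, SchemaError, Stage


def percent_change(treated_mean: float, control_mean: float) -> float:
    """100 * (treated - control) / control; control mean must be positive."""
    if control_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return 100.0 * (treated_mean - control_mean) / control_mean


def direction(pc: float, tol: float = 1e-12) -> str:
    if pc > tol:
        return "stimulation"
    if pc < -tol:
        return "inhibition"
    return "none"


_COLUMNS = ["endpoint", "stage", "tissue", "group", "value"]


@dataclass(frozen=True)
class EndpointTable:
    """Replicate endpoint measurements, one row per replicate.

    Columns: endpoint (free-text label), stage, tissue (or 'plant' for
    whole-plant measures), group (contaminated/control), value (> 0, in
    endpoint-specific units that must be consistent within an endpoint).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in _COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        df = df.copy()
        df["stage"] = [Stage(str(s)) for s in df["stage"]]
        df["group"] = [Group(str(g)) for g in df["group"]]
        vals = pd.to_numeric(df["value"], errors="coerce")
        if (vals.isna() | (vals <= 0)).any():
            idx = int(df.index[vals.isna() | (vals <= 0)][0])
            raise DataValidationError(f"non-positive or non-numeric endpoint value at row {idx}")
        df["value"] = vals.astype(float)
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "EndpointTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df["stage"] = [s.value for s in df["stage"]]
        df["group"] = [g.value for g in df["group"]]
        df[_COLUMNS].to_csv(path, index=False)


def endpoint_summary(table: EndpointTable) -> pd.DataFrame:
    """Percent-change report: one row per (endpoint, stage, tissue).

    Columns: percent_change (of group means), sd (SD of per-replicate
    percent changes relative to the control mean), n_treated, n_control,
    direction.  A treated group with no matching control raises an error
    naming the endpoint and stage.
    """
    df = table.data
    rows = []
    for (endpoint, stage, tissue), sub in df.groupby(
        ["endpoint", "stage", "tissue"], observed=True, sort=False
    ):
        treated = sub[sub["group"] == Group.CONTAMINATED]["value"]
        control = sub[sub["group"] == Group.CONTROL]["value"]
        if treated.empty:
            continue  # control-only endpoint: nothing to compare
        if control.empty:
            raise DataValidationError(
                f"no control group for endpoint {endpoint!r} at stage {stage.value}"
            )
        cm = float(control.mean())
        tm = float(treated.mean())
        pc = percent_change(tm, cm)
        per_rep = [percent_change(float(v), cm) for v in treated]
        if len(per_rep) > 1:
            mean_pc = sum(per_rep) / len(per_rep)
            sd = math.sqrt(sum((x - mean_pc) ** 2 for x in per_rep) / (len(per_rep) - 1))
        else:
            sd = float("nan")
        rows.append(
            dict(endpoint=endpoint, stage=stage.value, tissue=tissue,
                 percent_change=pc, sd=sd, n_treated=len(treated),
                 n_control=len(control), direction=direction(pc))
        )
    return pd.DataFrame(rows)
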