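"""Bioconcentration and translocation factors across the rice life cycle.

BF_root/soil = C_root / C_soil measures uptake from soil into roots;
TF_stem/root, TF_leaf/stem and TF_grain/stem measure stepwise transfer up
the plant.  Factors are dimensionless ratios of mg/kg DW concentrations.
Replicates are aggregated ratio-wise: each pot yields its own ratio, and
the table reports their mean +/- SD (not the ratio of mean concentrations).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .core_data import (
    DataValidationError,
    METAL_ORDER,
    Metal,
    MetalConcentrationTable,
    Stage,
    Tissue,
)


class FactorKind(str, enum.Enum):
    BF_ROOT_SOIL = "BF_root_soil"
    TF_STEM_ROOT = "TF_stem_root"
    TF_LEAF_STEM = "TF_leaf_stem"
    TF_GRAIN_STEM = "TF_grain_stem"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: numerator / denominator tissue per factor kind
FACTOR_TISSUES: Dict[FactorKind, Tuple[Tissue, Tissue]] = {
    FactorKind.BF_ROOT_SOIL: (Tissue.ROOT, Tissue.SOIL),
    FactorKind.TF_STEM_ROOT: (Tissue.STEM, Tissue.ROOT),
    FactorKind.TF_LEAF_STEM: (Tissue.LEAF, Tissue.STEM),
    FactorKind.TF_GRAIN_STEM: (Tissue.GRAIN, Tissue.STEM),
}


def compute_ratio(numerator: float, denominator: float) -> float:
    """Concentration ratio at full precision; denominator must be positive."""
    if denominator <= 0:
        raise ValueError(
            f"ratio undefined: denominator concentration {denominator} <= 0"
        )
    if numerator < 0:
        raise ValueError(f"negative numerator concentration {numerator}")
    return numerator / denominator


@dataclass(frozen=True)
class TransferFactorTable:
    """One record per (metal, stage, kind) with mean, SD and replicate count.

    A record is *absent* (value NaN, ``absent_reason`` set) exactly when the
    numerator tissue does not exist at that stage, e.g. grain at tillering.
    """

    data: pd.DataFrame  # columns: metal, stage, kind, value, sd, n, absent_reason

    def value(self, metal: Metal, stage: Stage, kind: FactorKind) -> Optional[float]:
        df = self.data
        row = df[(df["metal"] == metal) & (df["stage"] == stage) & (df["kind"] == kind)]
        if row.empty:
            return None
        v = row["value"].iloc[0]
        return None if pd.isna(v) else float(v)

    def to_csv(self, path) -> None:
        """Wide per-stage layout: metal, stage, one 'mean +/- sd' column per factor."""
        df = self.data.copy()
        df["cell"] = [
            "—" if pd.isna(v) else f"{v:.2f} ± {0.0 if pd.isna(s) else s:.2f}"
            for v, s in zip(df["value"], df["sd"])
        ]
        wide = df.pivot_table(
            index=["metal", "stage"], columns="kind", values="cell", aggfunc="first",
            observed=True,
        )
        wide = wide.reindex(columns=[k.value for k in FactorKind])
        out = wide.reset_index()
        out["metal"] = [m.value for m in out["metal"]]
        out["stage"] = [s.value for s in out["stage"]]
        out.to_csv(path, index=False)


def transfer_table(
    tissue: MetalConcentrationTable,
    soil: MetalConcentrationTable,
    kinds: Sequence[FactorKind] = tuple(FactorKind),
) -> TransferFactorTable:
    """Compute per-sample BF/TF ratios, then aggregate to mean +/- SD.

    Soil provides the BF denominator per (sample, metal); within-plant
    translocation factors pair tissues of the same (sample, stage, metal).
    Grain-based factors are flagged absent at stages with no grain records.
    """
    sdf = soil.data
    tdf = tissue.data
    soil_conc: Dict[Tuple[str, Metal], float] = {
        (r.sample_id, r.metal): r.concentration for r in sdf.itertuples()
    }
    tis_conc: Dict[Tuple[str, Stage, Tissue, Metal], float] = {
        (r.sample_id, r.stage, r.tissue, r.metal): r.concentration
        for r in tdf.itertuples()
    }
    stages = sorted({r.stage for r in tdf.itertuples()}, key=lambda s: list(Stage).index(s))
    metals = [m for m in METAL_ORDER if m in set(tdf["metal"])]
    samples = sorted({r.sample_id for r in tdf.itertuples()})

    records: List[dict] = []
    for stage in stages:
        for metal in metals:
            for kind in kinds:
                num_t, den_t = FACTOR_TISSUES[kind]
                ratios: List[float] = []
                for sid in samples:
                    num = tis_conc.get((sid, stage, num_t, metal))
                    if den_t == Tissue.SOIL:
                        den = soil_conc.get((sid, metal))
                    else:
                        den = tis_conc.get((sid, stage, den_t, metal))
                    if num is None or den is None:
                        continue
                    ratios.append(compute_ratio(num, den))
                if not ratios:
                    has_num = any(
                        k[1] == stage and k[2] == num_t and k[3] == metal
                        for k in tis_conc
                    )
                    reason = (
                        f"no {num_t.value} records at {stage.value}"
                        if not has_num
                        else f"no matching {den_t.value} denominator"
                    )
                    records.append(
                        dict(metal=metal, stage=stage, kind=kind, value=float("nan"),
                             sd=float("nan"), n=0, absent_reason=reason)
                    )
                    continue
                n = len(ratios)
                mean = sum(ratios) / n
                sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / (n - 1)) if n > 1 else float("nan")
                records.append(
                    dict(metal=metal, stage=stage, kind=kind, value=mean, sd=sd, n=n,
                         absent_reason=None)
                )
    return TransferFactorTable(pd.DataFrame.from_records(records))


def rank_metals(
    table: TransferFactorTable, kind: FactorKind, stage: Stage
) -> Tuple[List[Metal], bool]:
    """Metals sorted by descending factor value.

    Returns ``(ordering, had_ties)``; ties are broken by the canonical metal
    order (Cu, Cr, Zn, Cd, Pb, As).  Raises if any of the six metals has no
    value for (kind, stage).
    """
    values: Dict[Metal, float] = {}
    for m in METAL_ORDER:
        v = table.value(m, stage, kind)
        if v is None:
            raise DataValidationError(
                f"no {kind.value} value for {m.value} at {stage.value}; cannot rank"
            )
        values[m] = v
    order = sorted(METAL_ORDER, key=lambda m: (-values[m], METAL_ORDER.index(m)))
    vals = list(values.values())
    had_ties = len(set(vals)) < len(vals)
    return order, had_ties
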