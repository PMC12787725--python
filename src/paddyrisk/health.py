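"""Four-pathway human health risk: average daily intake, hazard quotients,
and carcinogenic risk for adult and child populations.

Exposure routes are rice consumption (food), incidental soil ingestion
(ing), inhalation of resuspended particles (inh) and dermal contact (der).
Average daily intake (mg/kg body weight/day):

    ADI_food = C_rice * IR * EF * ED / (BW * AT)
    ADI_ing  = C_soil * IngR * EF * ED / (BW * AT) * 1e-6
    ADI_inh  = C_soil * InhR * EF * ED / (PEF * BW * AT) * 1e-6
    ADI_der  = C_soil * SA * AF * ABS * EF * ED / (BW * AT) * 1e-6

The 1e-6 factor converts mg of soil to kg and applies only to the soil
pathways.  Non-carcinogenic hazard quotients HQ = ADI/RfD use the
non-carcinogenic averaging time AT_nc; carcinogenic risk CR = ADI * SF
averages over a lifetime (AT_ca).  HI and TCR sum HQ and CR over metals;
cells without an established slope factor are simply excluded.

All arithmetic is elementwise, so every function accepts scalars or numpy
arrays interchangeably — the Monte Carlo module feeds arrays through these
exact functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    METAL_ORDER,
    Metal,
    Pathway,
    PATHWAY_ORDER,
    ExposureParameterSet,
    ToxicologyReferenceSet,
)

HQ_THRESHOLD = 1.0
CR_UNACCEPTABLE = 1e-4
CR_NEGLIGIBLE = 1e-6


def _averaging_time(p: ExposureParameterSet, averaging: str) -> float:
    if averaging == "nc":
        return p.AT_nc
    if averaging == "ca":
        return p.AT_ca
    raise ValueError(f"averaging must be 'nc' or 'ca', got {averaging!r}")


def adi_food(c_rice, p: ExposureParameterSet, averaging: str = "nc"):
    """Daily intake through rice consumption, mg/kg/day."""
    at = _averaging_time(p, averaging)
    return c_rice * p.IR * p.EF * p.ED / (p.BW * at)


def adi_soil(c_soil, p: ExposureParameterSet, pathway: Pathway, averaging: str = "nc"):
    """Daily intake through a soil pathway (ing, inh or der), mg/kg/day."""
    pathway = Pathway(pathway)
    if pathway == Pathway.FOOD:
        raise ValueError("use adi_food for the rice-consumption pathway")
    at = _averaging_time(p, averaging)
    if pathway == Pathway.ING:
        return c_soil * p.IngR * p.EF * p.ED / (p.BW * at) * 1e-6
    if pathway == Pathway.INH:
        return c_soil * p.InhR * p.EF * p.ED / (p.PEF * p.BW * at) * 1e-6
    return c_soil * p.SA * p.AF * p.ABS * p.EF * p.ED / (p.BW * at) * 1e-6


def hazard_quotient(adi, rfd):
    """HQ = ADI / RfD."""
    if np.any(np.asarray(rfd) <= 0):
        raise ValueError(f"RfD must be > 0, got {rfd}")
    return adi / rfd


def carcinogenic_risk(adi, sf: Optional[float]):
    """CR = ADI * SF, or None when no slope factor exists for the cell."""
    if sf is None:
        return None
    return adi * sf


def classify_risk(value: float, kind: str) -> str:
    """Threshold labels; comparisons are strict (>1, >1e-4) so the boundary
    value itself sits on the no-risk / acceptable side."""
    if value < 0:
        raise ValueError(f"negative risk value {value}")
    if kind == "HQ_HI":
        return "risk" if value > HQ_THRESHOLD else "no potential risk"
    if kind == "CR_TCR":
        if value > CR_UNACCEPTABLE:
            return "unacceptable"
        if value >= CR_NEGLIGIBLE:
            return "acceptable"
        return "no obvious risk"
    raise ValueError(f"unknown risk kind {kind!r}")


@dataclass(frozen=True)
class RiskTable:
    """Per-cell HQ/CR with marginal totals, mirroring the familiar
    metal x pathway x population layout.

    ``cells`` has columns population, metal, pathway, hq, cr (cr is NaN
    where no slope factor exists); ``metal_totals`` carries hq_total and
    cr_total per (population, metal); ``grand`` carries HI and TCR per
    population.
    """

    cells: pd.DataFrame
    metal_totals: pd.DataFrame
    grand: pd.DataFrame

    def hi(self, population: str) -> float:
        return float(self.grand.set_index("population").loc[population, "hi"])

    def tcr(self, population: str) -> float:
        return float(self.grand.set_index("population").loc[population, "tcr"])

    def pathway_totals(self, population: str, quantity: str = "hq") -> Dict[Pathway, float]:
        """Column totals (sum over metals) for one population."""
        df = self.cells[self.cells["population"] == population]
        out: Dict[Pathway, float] = {}
        for p in PATHWAY_ORDER:
            col = df[df["pathway"] == p][quantity]
            out[p] = float(col.sum(skipna=True))
        return out

    def table3_frame(self) -> pd.DataFrame:
        """Wide layout: one row per (metal, population) with HQ_* and CR_*
        columns plus their totals; absent carcinogenic cells render as '—'."""
        rows = []
        mt = self.metal_totals.set_index(["population", "metal"])
        pops = list(dict.fromkeys(self.cells["population"]))
        metals = [m for m in METAL_ORDER if m in set(self.cells["metal"])]
        for metal in metals:
            for pop in pops:
                sub = self.cells[
                    (self.cells["population"] == pop) & (self.cells["metal"] == metal)
                ].set_index("pathway")
                row: Dict[str, object] = {"metal": metal.value, "population": pop}
                for p in PATHWAY_ORDER:
                    row[f"HQ_{p.value}"] = f"{sub.loc[p, 'hq']:.3g}"
                row["HQ_total"] = f"{mt.loc[(pop, metal), 'hq_total']:.3g}"
                cr_total = mt.loc[(pop, metal), "cr_total"]
                for p in PATHWAY_ORDER:
                    cr = sub.loc[p, "cr"]
                    row[f"CR_{p.value}"] = "—" if pd.isna(cr) else f"{cr:.3g}"
                row["CR_total"] = "—" if pd.isna(cr_total) else f"{cr_total:.3g}"
                rows.append(row)
        g = self.grand.set_index("population")
        for pop in pops:
            hq_cols = self.pathway_totals(pop, "hq")
            cr_cols = self.pathway_totals(pop, "cr")
            row = {"metal": "HI/TCR", "population": pop}
            for p in PATHWAY_ORDER:
                row[f"HQ_{p.value}"] = f"{hq_cols[p]:.3g}"
            row["HQ_total"] = f"{g.loc[pop, 'hi']:.3g}"
            for p in PATHWAY_ORDER:
                row[f"CR_{p.value}"] = f"{cr_cols[p]:.3g}"
            row["CR_total"] = f"{g.loc[pop, 'tcr']:.3g}"
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.table3_frame().to_csv(path, index=False)


def aggregate_risk(cells: pd.DataFrame) -> RiskTable:
    """Fill per-metal totals and grand HI/TCR from per-cell HQ/CR values.

    ``cells`` needs columns population, metal, pathway, hq and optionally
    cr (NaN/missing cr cells are skipped; a metal with no cr cell at all
    gets a NaN cr_total).  Sums are exact over the provided values.
    """
    df = cells.copy()
    if "cr" not in df.columns:
        df["cr"] = np.nan
    df["metal"] = [Metal(m) for m in df["metal"]]
    df["pathway"] = [Pathway(p) for p in df["pathway"]]

    # sums are sequential in row order so that results are reproducible
    # bit-for-bit by any caller accumulating in the same order
    totals = []
    for (pop, metal), sub in df.groupby(["population", "metal"], observed=True, sort=False):
        hq_total = 0.0
        for v in sub["hq"]:
            hq_total = hq_total + float(v)
        cr_vals = [float(v) for v in sub["cr"] if not pd.isna(v)]
        if cr_vals:
            cr_total = 0.0
            for v in cr_vals:
                cr_total = cr_total + v
        else:
            cr_total = np.nan
        totals.append(dict(population=pop, metal=metal, hq_total=hq_total, cr_total=cr_total))
    metal_totals = pd.DataFrame(totals)

    grand = []
    for pop, sub in metal_totals.groupby("population", sort=False):
        hi = 0.0
        for v in sub["hq_total"]:
            hi = hi + float(v)
        tcr = 0.0
        for v in sub["cr_total"]:
            if not pd.isna(v):
                tcr = tcr + float(v)
        grand.append(
            dict(population=pop, hi=hi, hi_class=classify_risk(hi, "HQ_HI"),
                 tcr=tcr, tcr_class=classify_risk(tcr, "CR_TCR"))
        )
    return RiskTable(cells=df, metal_totals=metal_totals, grand=pd.DataFrame(grand))


def compute_risk_table(
    c_rice: Mapping[Metal, float],
    c_soil: Mapping[Metal, float],
    exposures: Mapping[str, ExposureParameterSet],
    toxref: ToxicologyReferenceSet,
    metals: Sequence[Metal] = METAL_ORDER,
) -> RiskTable:
    """Deterministic end-to-end risk table from mean concentrations.

    HQ uses the non-carcinogenic averaging time, CR the carcinogenic one.
    ``c_rice`` is grain concentration (mg/kg DW), ``c_soil`` total soil
    concentration (mg/kg DW).
    """
    rows = []
    for pop, p in exposures.items():
        for m in metals:
            for path in PATHWAY_ORDER:
                if path == Pathway.FOOD:
                    adi_nc = adi_food(c_rice[m], p, "nc")
                    adi_ca = adi_food(c_rice[m], p, "ca")
                else:
                    adi_nc = adi_soil(c_soil[m], p, path, "nc")
                    adi_ca = adi_soil(c_soil[m], p, path, "ca")
                hq = hazard_quotient(adi_nc, toxref.get_rfd(m, path))
                cr = carcinogenic_risk(adi_ca, toxref.get_sf(m, path))
                rows.append(
                    dict(population=pop, metal=m, pathway=path,
                         adi_nc=adi_nc, adi_ca=adi_ca, hq=hq,
                         cr=np.nan if cr is None else cr)
                )
    return aggregate_risk(pd.DataFrame(rows))
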