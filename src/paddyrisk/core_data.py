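"""Shared domain types for the soil-rice heavy-metal assessment.

Everything downstream (transfer factors, pollution/ecological indices,
health risk, Monte Carlo) consumes the validated containers defined here.
All concentrations are mg/kg dry weight throughout; no unit conversion
happens anywhere in the pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


class DataValidationError(ValueError):
    """A table parsed but violates a domain invariant (negative value, unknown metal, ...)."""


class Metal(str, enum.Enum):
    """The six metals assessed; the set is closed and unknown symbols are rejected."""

    CU = "Cu"
    CR = "Cr"
    ZN = "Zn"
    CD = "Cd"
    PB = "Pb"
    AS = "As"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering, used for deterministic output and tie-breaking.
METAL_ORDER: tuple = tuple(Metal)


class Stage(str, enum.Enum):
    TILLERING = "tillering"
    HEADING = "heading"
    MATURITY = "maturity"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Tissue(str, enum.Enum):
    SOIL = "soil"
    ROOT = "root"
    STEM = "stem"
    LEAF = "leaf"
    GRAIN = "grain"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Group(str, enum.Enum):
    CONTAMINATED = "contaminated"
    CONTROL = "control"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class Pathway(str, enum.Enum):
    """Exposure pathways: rice consumption, soil ingestion, inhalation, dermal contact."""

    FOOD = "food"
    ING = "ing"
    INH = "inh"
    DER = "der"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


PATHWAY_ORDER: tuple = tuple(Pathway)


def parse_metal(symbol: str) -> Metal:
    try:
        return Metal(str(symbol).strip())
    except ValueError:
        raise DataValidationError(
            f"unknown metal symbol {symbol!r}; expected one of "
            f"{[m.value for m in Metal]}"
        ) from None


# ---------------------------------------------------------------------------
# Concentration tables
# ---------------------------------------------------------------------------

_SOIL_COLUMNS = ["sample_id", "group", "metal", "concentration"]
_TISSUE_COLUMNS = ["sample_id", "group", "stage", "tissue", "metal", "concentration"]


@dataclass(frozen=True)
class MetalConcentrationTable:
    """Soil or plant-tissue concentrations, mg/kg dry weight.

    ``kind='soil'`` tables have no stage and tissue fixed to ``soil``;
    ``kind='tissue'`` tables carry (stage, tissue) per record.  The key
    (sample_id, stage, tissue, metal) is unique and grain records never
    occur at tillering (no grain exists before heading).
    """

    data: pd.DataFrame
    kind: str = "soil"

    def __post_init__(self) -> None:
        df = self.data
        required = _SOIL_COLUMNS if self.kind == "soil" else _TISSUE_COLUMNS
        for col in required:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r} for kind={self.kind!r}")
        df = df.copy()
        df["metal"] = [parse_metal(m) for m in df["metal"]]
        df["group"] = [Group(str(g).strip()) for g in df["group"]]
        if self.kind == "soil":
            df["stage"] = None
            df["tissue"] = Tissue.SOIL
        else:
            df["stage"] = [Stage(str(s).strip()) for s in df["stage"]]
            df["tissue"] = [Tissue(str(t).strip()) for t in df["tissue"]]
        conc = pd.to_numeric(df["concentration"], errors="coerce")
        bad = conc.isna() | (conc < 0)
        if bad.any():
            idx = int(df.index[bad][0])
            raise DataValidationError(
                f"non-numeric or negative concentration at row {idx}: "
                f"{df.loc[idx, 'concentration']!r}"
            )
        df["concentration"] = conc.astype(float)
        key = ["sample_id", "stage", "tissue", "metal"]
        dup = df.duplicated(subset=key)
        if dup.any():
            idx = int(df.index[dup][0])
            raise DataValidationError(f"duplicate (sample, stage, tissue, metal) key at row {idx}")
        grain_at_tillering = (df["tissue"] == Tissue.GRAIN) & (df["stage"] == Stage.TILLERING)
        if grain_at_tillering.any():
            idx = int(df.index[grain_at_tillering][0])
            raise DataValidationError(f"grain record at tillering stage (row {idx}); grain does not exist before heading")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, *, group: Optional[Group] = None, stage: Optional[Stage] = None,
               tissue: Optional[Tissue] = None) -> "MetalConcentrationTable":
        df = self.data
        if group is not None:
            df = df[df["group"] == group]
        if stage is not None:
            df = df[df["stage"] == stage]
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        return MetalConcentrationTable(df.reset_index(drop=True), kind=self.kind)

    def mean_by_metal(self) -> Dict[Metal, float]:
        """Mean concentration per metal over all records in the table."""
        g = self.data.groupby("metal", observed=True)["concentration"].mean()
        return {m: float(g[m]) for m in g.index}

    def to_csv(self, path: Union[str, Path]) -> None:
        df = self.data.copy()
        cols = _SOIL_COLUMNS if self.kind == "soil" else _TISSUE_COLUMNS
        for c in ("metal", "group", "stage", "tissue"):
            if c in cols:
                df[c] = [v.value if v is not None else "" for v in df[c]]
        df[cols].to_csv(path, index=False)


def load_concentration_table(path: Union[str, Path], kind: str = "soil") -> MetalConcentrationTable:
    """Read a concentration CSV (RFC-4180, UTF-8) and validate it.

    Soil files need columns sample_id, group, metal, concentration;
    tissue files additionally need stage and tissue.
    """
    if kind not in ("soil", "tissue"):
        raise ValueError(f"kind must be 'soil' or 'tissue', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip parsing keeps write->read of concentrations bit-identical
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if df.empty and df.columns.size == 0:
        raise SchemaError(f"{path} has no header row")
    return MetalConcentrationTable(df, kind=kind)


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------


class ScreeningStandardSet(BaseModel):
    """Regulatory soil screening values S_i (mg/kg) used by the pollution indices."""

    model_config = ConfigDict(frozen=True)

    values: Dict[Metal, float]
    provenance: str = ""

    @model_validator(mode="after")
    def _positive(self) -> "ScreeningStandardSet":
        for m, v in self.values.items():
            if not v > 0:
                raise ValueError(f"screening standard for {m.value} must be > 0, got {v}")
        return self


class ToxicResponseFactorSet(BaseModel):
    """Hakanson toxic response factors T_i (dimensionless)."""

    model_config = ConfigDict(frozen=True)

    values: Dict[Metal, float] = Field(
        default_factory=lambda: {
            Metal.CD: 30.0,
            Metal.AS: 10.0,
            Metal.PB: 5.0,
            Metal.CU: 5.0,
            Metal.CR: 2.0,
            Metal.ZN: 1.0,
        }
    )

    @model_validator(mode="after")
    def _positive(self) -> "ToxicResponseFactorSet":
        for m, v in self.values.items():
            if not v > 0:
                raise ValueError(f"toxic response factor for {m.value} must be > 0, got {v}")
        return self


class ExposureParameterSet(BaseModel):
    """Per-population exposure constants for the daily-intake equations.

    IR    rice intake, kg/day
    IngR  incidental soil ingestion, mg/day
    InhR  inhalation rate, m3/day
    EF    exposure frequency, days/year
    ED    exposure duration, years
    BW    body weight, kg
    AT_nc averaging time for non-carcinogenic effects, days (typically ED*365)
    AT_ca averaging time for carcinogenic effects, days (lifetime, 70*365)
    SA    exposed skin surface area, cm2
    AF    soil-to-skin adherence factor, mg/cm2/day
    ABS   dermal absorption fraction, unitless in (0, 1]
    PEF   particle emission factor, m3/kg
    """

    model_config = ConfigDict(frozen=True)

    population: str
    IR: float = Field(gt=0)
    IngR: float = Field(gt=0)
    InhR: float = Field(gt=0)
    EF: float = Field(gt=0)
    ED: float = Field(gt=0)
    BW: float = Field(gt=0)
    AT_nc: float = Field(gt=0)
    AT_ca: float = Field(gt=0)
    SA: float = Field(gt=0)
    AF: float = Field(gt=0)
    ABS: float = Field(gt=0, le=1)
    PEF: float = Field(gt=0)

    @model_validator(mode="after")
    def _averaging_times(self) -> "ExposureParameterSet":
        floor = self.ED * 365.0
        if self.AT_nc < floor or self.AT_ca < floor:
            raise ValueError(
                f"averaging times must be >= ED*365 = {floor} days "
                f"(got AT_nc={self.AT_nc}, AT_ca={self.AT_ca})"
            )
        return self


class ToxicologyReferenceSet(BaseModel):
    """Reference doses (RfD, mg/kg/day) and cancer slope factors (SF, (mg/kg/day)^-1).

    RfD must exist for every (metal, pathway) a hazard quotient is computed
    for.  SF is a partial map: pathways without an established slope factor
    (e.g. dermal Pb) simply have no entry and are excluded from carcinogenic
    sums; metals with no SF at all contribute no carcinogenic rows.
    """

    model_config = ConfigDict(frozen=True)

    rfd: Dict[Metal, Dict[Pathway, float]]
    sf: Dict[Metal, Dict[Pathway, float]] = Field(default_factory=dict)
    provenance: str = ""

    @model_validator(mode="after")
    def _positive(self) -> "ToxicologyReferenceSet":
        for table, name in ((self.rfd, "RfD"), (self.sf, "SF")):
            for m, per_path in table.items():
                for p, v in per_path.items():
                    if not v > 0:
                        raise ValueError(f"{name}({m.value}, {p.value}) must be > 0, got {v}")
        return self

    def get_rfd(self, metal: Metal, pathway: Pathway) -> float:
        try:
            return self.rfd[metal][pathway]
        except KeyError:
            raise KeyError(f"no RfD for ({metal.value}, {pathway.value})") from None

    def get_sf(self, metal: Metal, pathway: Pathway) -> Optional[float]:
        return self.sf.get(metal, {}).get(pathway)


# ---------------------------------------------------------------------------
# Cross-cutting validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only result of checking parameter completeness before a run."""

    missing: List[tuple] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing

    def __str__(self) -> str:
        lines = [f"MISSING {metal}: {what}" for metal, what in self.missing]
        lines += [f"NOTE: {n}" for n in self.notes]
        return "\n".join(lines) if lines else "OK: all parameter sets complete"


def validate_parameter_sets(
    std: ScreeningStandardSet,
    tox: ToxicResponseFactorSet,
    exp: Iterable[ExposureParameterSet],
    ref: ToxicologyReferenceSet,
    metals: Sequence[Metal] = METAL_ORDER,
) -> ValidationReport:
    """List every (metal, parameter) pair missing for an end-to-end run.

    An empty ``missing`` list means the full pipeline can execute.  Absent
    slope factors are legitimate (they exclude cells from carcinogenic
    sums) and are reported as notes, never as failures.
    """
    report = ValidationReport()
    for m in metals:
        if m not in std.values:
            report.missing.append((m.value, "screening standard"))
        if m not in tox.values:
            report.missing.append((m.value, "toxic response factor"))
        for p in Pathway:
            if ref.rfd.get(m, {}).get(p) is None:
                report.missing.append((m.value, f"RfD[{p.value}]"))
            if ref.get_sf(m, p) is None:
                report.notes.append(
                    f"no SF for ({m.value}, {p.value}); cell excluded from carcinogenic totals"
                )
    for e in exp:
        # pydantic already enforces positivity; presence of both populations
        # is the caller's concern, noted if only one supplied
        pass
    pops = {e.population for e in exp}
    for want in ("adult", "child"):
        if want not in pops:
            report.notes.append(f"no exposure parameter set for population '{want}'")
    return report
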