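"""Soil pollution and ecological risk indices.

Single-metal pollution index PI = C_i / S_i compares each metal's soil
concentration with its regulatory screening value.  The Nemerow composite
NIPI = sqrt((PI_mean^2 + PI_max^2) / 2) emphasises the worst metal.  The
Hakanson single-metal ecological index EI = T_i * PI weights pollution by
a metal-specific toxic response factor, and the integrated risk RI is the
sum of EI over metals.

Classification bands follow standard Nemerow/Hakanson conventions and are
config-overridable; all boundaries are half-open [lower, upper).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .core_data import (
    METAL_ORDER,
    Metal,
    ScreeningStandardSet,
    ToxicResponseFactorSet,
)

# (lower, upper, label) with value classified into the band where
# lower <= value < upper
BandTable = Sequence[Tuple[float, float, str]]

_INF = math.inf

DEFAULT_BANDS: Dict[str, BandTable] = {
    "PI": (
        (0.0, 1.0, "unpolluted"),
        (1.0, 2.0, "low"),
        (2.0, 3.0, "moderate"),
        (3.0, _INF, "high"),
    ),
    "NIPI": (
        (0.0, 0.7, "safe"),
        (0.7, 1.0, "warning"),
        (1.0, 2.0, "light"),
        (2.0, 3.0, "moderate"),
        (3.0, _INF, "high"),
    ),
    "EI": (
        (0.0, 40.0, "low"),
        (40.0, 80.0, "moderate"),
        (80.0, 160.0, "considerable"),
        (160.0, 320.0, "high"),
        (320.0, _INF, "very high"),
    ),
    "RI": (
        (0.0, 150.0, "low"),
        (150.0, 300.0, "moderate"),
        (300.0, 600.0, "considerable"),
        (600.0, _INF, "very high"),
    ),
}


def pollution_index(ci: float, si: float) -> float:
    """PI = C_i / S_i at full precision."""
    if si <= 0:
        raise ValueError(f"screening value must be > 0, got {si}")
    if ci < 0:
        raise ValueError(f"negative concentration {ci}")
    return ci / si


def nemerow_index(pis: Sequence[float]) -> float:
    """Nemerow composite sqrt((mean^2 + max^2)/2) over single-metal PI values."""
    if len(pis) == 0:
        raise ValueError("Nemerow index undefined for an empty PI list")
    if any(p < 0 for p in pis):
        raise ValueError("PI values must be >= 0")
    ave = sum(pis) / len(pis)
    mx = max(pis)
    return math.sqrt((ave * ave + mx * mx) / 2.0)


def ecological_index(pi: float, ti: float) -> float:
    """Hakanson single-metal index EI = T_i * PI."""
    if ti <= 0:
        raise ValueError(f"toxic response factor must be > 0, got {ti}")
    if pi < 0:
        raise ValueError(f"negative pollution index {pi}")
    return ti * pi


def risk_index(eis: Sequence[float]) -> float:
    """Integrated ecological risk RI = sum of single-metal EI values."""
    if len(eis) == 0:
        raise ValueError("risk index undefined for an empty EI list")
    if any(e < 0 for e in eis):
        raise ValueError("EI values must be >= 0")
    return float(sum(eis))


def classify(value: float, scheme: str, bands: Mapping[str, BandTable] = DEFAULT_BANDS) -> str:
    """Label ``value`` using the band table for ``scheme`` (PI, NIPI, EI or RI)."""
    if scheme not in bands:
        raise ValueError(f"unknown classification scheme {scheme!r}")
    if value < 0:
        raise ValueError(f"negative index value {value}")
    for lower, upper, label in bands[scheme]:
        if lower <= value < upper:
            return label
    raise ValueError(f"value {value} falls outside every {scheme} band")  # pragma: no cover


@dataclass(frozen=True)
class IndexResult:
    """Per-metal PI/EI with class labels plus the NIPI and RI composites."""

    per_metal: Dict[Metal, Dict[str, object]]
    nipi: float
    nipi_class: str
    ri: float
    ri_class: str
    screening_provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, d in self.per_metal.items():
            rows.append(
                dict(metal=m.value, pi=d["pi"], pi_class=d["pi_class"],
                     ei=d["ei"], ei_class=d["ei_class"])
            )
        return pd.DataFrame(rows)

    def summary_line(self) -> str:
        return (
            f"NIPI={self.nipi:.2f} ({self.nipi_class}); RI={self.ri:.2f} ({self.ri_class}); "
            f"screening set: {self.screening_provenance or 'unspecified'}"
        )


def assess_soil(
    concentrations: Mapping[Metal, float],
    standards: ScreeningStandardSet,
    tox: ToxicResponseFactorSet,
    bands: Mapping[str, BandTable] = DEFAULT_BANDS,
) -> IndexResult:
    """Full index chain for one set of mean soil concentrations.

    The invariants EI = T_i * PI and RI = sum(EI) hold exactly because the
    composites are computed from the very same per-metal values reported.
    """
    metals = [m for m in METAL_ORDER if m in concentrations]
    per_metal: Dict[Metal, Dict[str, object]] = {}
    pis: List[float] = []
    eis: List[float] = []
    for m in metals:
        if m not in standards.values:
            raise KeyError(f"no screening standard for {m.value}")
        if m not in tox.values:
            raise KeyError(f"no toxic response factor for {m.value}")
        pi = pollution_index(concentrations[m], standards.values[m])
        ei = ecological_index(pi, tox.values[m])
        per_metal[m] = dict(
            pi=pi, pi_class=classify(pi, "PI", bands),
            ei=ei, ei_class=classify(ei, "EI", bands),
        )
        pis.append(pi)
        eis.append(ei)
    nipi = nemerow_index(pis)
    ri = risk_index(eis)
    return IndexResult(
        per_metal=per_metal,
        nipi=nipi,
        nipi_class=classify(nipi, "NIPI", bands),
        ri=ri,
        ri_class=classify(ri, "RI", bands),
        screening_provenance=standards.provenance,
    )
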