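"""Shared fixtures: published study-site values used as test oracles."""

import pandas as pd
import pytest

from paddyrisk import Metal

# Single-metal pollution indices of the contaminated plot (dimensionless),
# as published for the study site.
PRINTED_PI = {
    Metal.AS: 5.92,
    Metal.PB: 4.66,
    Metal.CD: 3.35,
    Metal.ZN: 1.96,
    Metal.CU: 0.65,
    Metal.CR: 0.32,
}

# Published single-metal ecological indices (EI = Ti * PI).
PRINTED_EI = {
    Metal.CD: 100.43,
    Metal.AS: 59.24,
    Metal.PB: 23.30,
    Metal.CU: 3.26,
    Metal.ZN: 1.96,
    Metal.CR: 0.65,
}

# Published per-cell hazard quotients and carcinogenic risks
# (metal, population) -> {"hq": (food, ing, inh, der), "cr": (...) or None per cell}.
PRINTED_RISK_CELLS = {
    ("Cu", "adult"): {"hq": (7.72e-1, 5.21e-4, 3.05e-14, 3.46e-5), "cr": None},
    ("Cu", "child"): {"hq": (1.61, 3.19e-3, 3.55e-14, 1.19e-4), "cr": None},
    ("Cr", "adult"): {"hq": (11.63, 7.43e-3, 4.59e-10, 1.48e-4),
                      "cr": (1.74e-2, 1.11e-5, 5.51e-13, 8.90e-6)},
    ("Cr", "child"): {"hq": (24.38, 4.55e-2, 5.33e-10, 5.10e-4),
                      "cr": (3.66e-2, 6.82e-5, 6.41e-13, 3.06e-5)},
    ("Zn", "adult"): {"hq": (1.01, 5.23e-4, 3.08e-13, 5.22e-5), "cr": None},
    ("Zn", "child"): {"hq": (2.12, 3.20e-3, 3.58e-13, 1.79e-4), "cr": None},
    ("Cd", "adult"): {"hq": (1.93, 6.42e-4, 3.78e-13, 1.28e-3),
                      "cr": (1.18e-2, 3.92e-6, 2.38e-15, 7.81e-8)},
    ("Cd", "child"): {"hq": (4.05, 3.93e-3, 4.39e-13, 4.40e-3),
                      "cr": (2.47e-2, 2.40e-5, 2.77e-15, 2.69e-7)},
    ("Pb", "adult"): {"hq": (5.38, 5.96e-2, 3.48e-11, 7.92e-3),
                      "cr": (1.60e-4, 1.77e-6, 5.15e-15, None)},
    ("Pb", "child"): {"hq": (11.27, 3.65e-1, 4.05e-11, 2.72e-2),
                      "cr": (3.35e-4, 1.09e-5, 5.99e-15, None)},
    ("As", "adult"): {"hq": (28.23, 1.58e-1, 2.26e-10, 2.30e-1),
                      "cr": (1.27e-2, 7.10e-5, 4.20e-13, 1.04e-4)},
    ("As", "child"): {"hq": (59.18, 9.66e-1, 2.63e-10, 7.92e-1),
                      "cr": (2.66e-2, 4.35e-4, 4.89e-13, 3.56e-4)},
}

_PATHWAYS = ("food", "ing", "inh", "der")


def printed_risk_cells_frame() -> pd.DataFrame:
    """The published per-cell values as an aggregate_risk input frame."""
    rows = []
    for (metal, pop), cell in PRINTED_RISK_CELLS.items():
        for i, path in enumerate(_PATHWAYS):
            cr = cell["cr"][i] if cell["cr"] is not None else None
            rows.append(dict(population=pop, metal=metal, pathway=path,
                             hq=cell["hq"][i], cr=cr))
    return pd.DataFrame(rows)


@pytest.fixture
def printed_cells():
    return printed_risk_cells_frame()


@pytest.fixture
def printed_pi():
    return dict(PRINTED_PI)


@pytest.fixture
def printed_ei():
    return dict(PRINTED_EI)
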