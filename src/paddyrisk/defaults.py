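"""Packaged default parameter tables.

Every default here is explicit config: reports echo the set actually used,
and any value can be overridden from a YAML config file.  Provenance notes
travel with each set.
"""

from __future__ import annotations

from typing import Dict

from .core_data import (
    ExposureParameterSet,
    Metal,
    Pathway,
    ScreeningStandardSet,
    Stage,
    ToxicResponseFactorSet,
    ToxicologyReferenceSet,
)

# ---------------------------------------------------------------------------
# Screening standards (S_i, mg/kg)
# ---------------------------------------------------------------------------

#: GB 15618-2018 risk screening values for paddy fields, pH band 5.5-6.5.
GB15618_PADDY_PH_5P5_6P5 = ScreeningStandardSet(
    values={
        Metal.CD: 0.4,
        Metal.PB: 100.0,
        Metal.CR: 250.0,
        Metal.CU: 50.0,
        Metal.ZN: 200.0,
        Metal.AS: 30.0,
    },
    provenance="GB 15618-2018 risk screening values, paddy field, 5.5 < pH <= 6.5",
)

#: GB 15618-2018 risk screening values for paddy fields, pH band 6.5-7.5.
GB15618_PADDY_PH_6P5_7P5 = ScreeningStandardSet(
    values={
        Metal.CD: 0.6,
        Metal.PB: 140.0,
        Metal.CR: 300.0,
        Metal.CU: 100.0,
        Metal.ZN: 250.0,
        Metal.AS: 25.0,
    },
    provenance="GB 15618-2018 risk screening values, paddy field, 6.5 < pH <= 7.5",
)

#: Synthetic reconstruction: screening values back-calculated from the study
#: site's mean soil concentrations and its published single-metal pollution
#: indices.  Five of six match the GB 15618-2018 paddy 6.5-7.5 band; Cr (~218)
#: matches no GB band and is kept as reconstructed.  Use for reproducing the
#: study-site index chain, not as a regulatory set.
STUDY_BACKCALCULATED = ScreeningStandardSet(
    values={
        Metal.CU: 100.0,
        Metal.CR: 218.0,
        Metal.ZN: 250.0,
        Metal.CD: 0.6,
        Metal.PB: 140.0,
        Metal.AS: 25.0,
    },
    provenance="synthetic: back-calculated from site mean concentrations and published PI values",
)

SCREENING_SETS: Dict[str, ScreeningStandardSet] = {
    "gb15618_paddy_ph_5.5_6.5": GB15618_PADDY_PH_5P5_6P5,
    "gb15618_paddy_ph_6.5_7.5": GB15618_PADDY_PH_6P5_7P5,
    "study_backcalculated": STUDY_BACKCALCULATED,
}

# ---------------------------------------------------------------------------
# Hakanson toxic response factors
# ---------------------------------------------------------------------------

TOXIC_RESPONSE_DEFAULT = ToxicResponseFactorSet()  # Cd 30, As 10, Pb 5, Cu 5, Cr 2, Zn 1

# ---------------------------------------------------------------------------
# Exposure parameters
# ---------------------------------------------------------------------------

# Standard adult/child residential exposure constants (US EPA Exposure Factors
# Handbook / HJ 25.3 technical guideline conventions widely used in Chinese
# soil health-risk studies).
EXPOSURE_ADULT = ExposureParameterSet(
    population="adult",
    IR=0.3,          # kg rice/day
    IngR=100.0,      # mg soil/day
    InhR=14.5,       # m3/day
    EF=350.0,        # days/year
    ED=24.0,         # years
    BW=60.0,         # kg
    AT_nc=24.0 * 365.0,
    AT_ca=70.0 * 365.0,
    SA=5700.0,       # cm2
    AF=0.07,         # mg/cm2/day
    ABS=0.001,
    PEF=1.36e9,      # m3/kg
)

EXPOSURE_CHILD = ExposureParameterSet(
    population="child",
    IR=0.2,
    IngR=200.0,
    InhR=7.5,
    EF=350.0,
    ED=6.0,
    BW=16.0,
    AT_nc=6.0 * 365.0,
    AT_ca=70.0 * 365.0,
    SA=2800.0,
    AF=0.2,
    ABS=0.001,
    PEF=1.36e9,
)

EXPOSURE_DEFAULTS: Dict[str, ExposureParameterSet] = {
    "adult": EXPOSURE_ADULT,
    "child": EXPOSURE_CHILD,
}

# ---------------------------------------------------------------------------
# Toxicological reference values
# ---------------------------------------------------------------------------

_F, _I, _H, _D = Pathway.FOOD, Pathway.ING, Pathway.INH, Pathway.DER

# RfD in mg/kg/day.  Oral values from US EPA IRIS; inhalation from RfC
# conversions; dermal = oral x gastrointestinal absorption fraction, as
# conventionally tabulated in soil risk assessments.
TOXREF_DEFAULT = ToxicologyReferenceSet(
    rfd={
        Metal.CU: {_F: 0.04, _I: 0.04, _H: 0.0402, _D: 0.012},
        Metal.CR: {_F: 0.003, _I: 0.003, _H: 2.86e-5, _D: 6.0e-5},
        Metal.ZN: {_F: 0.3, _I: 0.3, _H: 0.3, _D: 0.06},
        Metal.CD: {_F: 0.001, _I: 0.001, _H: 0.001, _D: 1.0e-5},
        Metal.PB: {_F: 0.0035, _I: 0.0035, _H: 0.00352, _D: 5.25e-4},
        Metal.AS: {_F: 3.0e-4, _I: 3.0e-4, _H: 3.01e-4, _D: 1.23e-4},
    },
    # Slope factors in (mg/kg/day)^-1.  Cu and Zn have none (no carcinogenic
    # rows); Pb has no dermal SF, so that cell is absent from totals.
    sf={
        Metal.CR: {_F: 0.5, _I: 0.5, _H: 42.0, _D: 20.0},
        Metal.CD: {_F: 6.1, _I: 6.1, _H: 6.3, _D: 6.1},
        Metal.PB: {_F: 0.0085, _I: 0.0085, _H: 0.042},
        Metal.AS: {_F: 1.5, _I: 1.5, _H: 15.1, _D: 3.66},
    },
    provenance="US EPA IRIS / RSL conventions; dermal RfD = oral x GI absorption",
)

# ---------------------------------------------------------------------------
# Study-site calibration values for the synthetic generator
# ---------------------------------------------------------------------------

#: Mean soil concentrations (mg/kg DW), contaminated plot.
SOIL_MEANS_CONTAMINATED: Dict[Metal, float] = {
    Metal.CU: 65.18,
    Metal.CR: 69.75,
    Metal.ZN: 490.87,
    Metal.CD: 2.01,
    Metal.PB: 652.34,
    Metal.AS: 148.11,
}

#: Mean soil concentrations (mg/kg DW), uncontaminated control plot.
SOIL_MEANS_CONTROL: Dict[Metal, float] = {
    Metal.CU: 23.98,
    Metal.CR: 38.46,
    Metal.ZN: 123.94,
    Metal.CD: 0.27,
    Metal.PB: 31.92,
    Metal.AS: 13.08,
}

#: Replicate standard deviations of the contaminated soil means (mg/kg DW);
#: the generator turns these into per-metal coefficients of variation.
SOIL_SD_CONTAMINATED: Dict[Metal, float] = {
    Metal.CU: 4.03,
    Metal.CR: 2.96,
    Metal.ZN: 15.84,
    Metal.CD: 0.29,
    Metal.PB: 29.73,
    Metal.AS: 8.07,
}

#: True transfer factors per (metal, stage): bioconcentration root/soil and
#: translocation stem/root, leaf/stem, grain/stem.  Grain factors do not
#: exist at tillering.  Keys of the inner dict are factor-kind names used by
#: the accumulation module.
_T, _HD, _M = Stage.TILLERING, Stage.HEADING, Stage.MATURITY

TRUE_FACTORS_DEFAULT: Dict[Metal, Dict[Stage, Dict[str, float]]] = {
    Metal.CU: {
        _T: {"BF_root_soil": 0.38, "TF_stem_root": 0.27, "TF_leaf_stem": 1.34},
        _HD: {"BF_root_soil": 0.49, "TF_stem_root": 0.28, "TF_leaf_stem": 0.84, "TF_grain_stem": 0.66},
        _M: {"BF_root_soil": 0.60, "TF_stem_root": 0.16, "TF_leaf_stem": 0.81, "TF_grain_stem": 0.91},
    },
    Metal.CR: {
        _T: {"BF_root_soil": 0.53, "TF_stem_root": 0.41, "TF_leaf_stem": 0.95},
        _HD: {"BF_root_soil": 0.46, "TF_stem_root": 0.52, "TF_leaf_stem": 1.28, "TF_grain_stem": 0.51},
        _M: {"BF_root_soil": 0.35, "TF_stem_root": 0.53, "TF_leaf_stem": 1.35, "TF_grain_stem": 0.50},
    },
    Metal.ZN: {
        _T: {"BF_root_soil": 0.44, "TF_stem_root": 0.36, "TF_leaf_stem": 1.20},
        _HD: {"BF_root_soil": 0.33, "TF_stem_root": 0.43, "TF_leaf_stem": 0.97, "TF_grain_stem": 0.80},
        _M: {"BF_root_soil": 0.52, "TF_stem_root": 0.36, "TF_leaf_stem": 1.14, "TF_grain_stem": 0.61},
    },
    Metal.CD: {
        _T: {"BF_root_soil": 0.79, "TF_stem_root": 0.47, "TF_leaf_stem": 0.65},
        _HD: {"BF_root_soil": 1.04, "TF_stem_root": 0.35, "TF_leaf_stem": 0.44, "TF_grain_stem": 0.52},
        _M: {"BF_root_soil": 1.95, "TF_stem_root": 0.17, "TF_leaf_stem": 0.61, "TF_grain_stem": 0.55},
    },
    Metal.PB: {
        _T: {"BF_root_soil": 0.44, "TF_stem_root": 0.04, "TF_leaf_stem": 1.31},
        _HD: {"BF_root_soil": 0.46, "TF_stem_root": 0.06, "TF_leaf_stem": 0.90, "TF_grain_stem": 0.13},
        _M: {"BF_root_soil": 0.75, "TF_stem_root": 0.05, "TF_leaf_stem": 0.51, "TF_grain_stem": 0.14},
    },
    Metal.AS: {
        _T: {"BF_root_soil": 0.45, "TF_stem_root": 0.33, "TF_leaf_stem": 1.09},
        _HD: {"BF_root_soil": 0.42, "TF_stem_root": 0.36, "TF_leaf_stem": 0.87, "TF_grain_stem": 0.09},
        _M: {"BF_root_soil": 0.32, "TF_stem_root": 0.38, "TF_leaf_stem": 1.07, "TF_grain_stem": 0.09},
    },
}

# ---------------------------------------------------------------------------
# Phytotoxicity endpoint calibration
# ---------------------------------------------------------------------------

#: Percent change of each endpoint in contaminated vs control plants at the
#: three growth stages (negative = inhibition).  Tissue is "plant" for
#: whole-plant morphometrics.
ENDPOINT_EFFECTS_DEFAULT: Dict[tuple, Dict[Stage, float]] = {
    ("plant_height", "plant"): {_T: -31.4, _HD: -28.8, _M: -27.8},
    ("root_length", "plant"): {_T: -31.7, _HD: -29.4, _M: -21.6},
    ("aboveground_dry_weight", "plant"): {_T: -44.7, _HD: -27.1, _M: -33.5},
    ("root_dry_weight", "plant"): {_T: -28.4, _HD: -46.4, _M: -60.6},
    ("tiller_number", "plant"): {_T: -31.7, _HD: -33.2, _M: -50.0},
    ("panicle_emergence", "plant"): {_T: -29.2, _HD: -34.3, _M: -42.0},
    ("MDA", "root"): {_T: 11.0, _HD: 28.9, _M: 18.0},
    ("MDA", "stem"): {_T: 81.2, _HD: 116.6, _M: 30.4},
    ("MDA", "leaf"): {_T: 16.8, _HD: 26.4, _M: 6.3},
    ("SOD", "root"): {_T: 24.3, _HD: 37.3, _M: -30.7},
    ("Glu", "rhizosphere"): {_T: 65.4, _HD: 155.9, _M: 211.8},
}

#: Control-group means per endpoint in plausible units (cm, g, counts,
#: nmol/g FW, U/g FW, mg/kg soil); arbitrary but realistic anchors for the
#: generator's percent-change structure.
ENDPOINT_CONTROL_MEANS: Dict[tuple, Dict[Stage, float]] = {
    ("plant_height", "plant"): {_T: 65.0, _HD: 95.0, _M: 105.0},
    ("root_length", "plant"): {_T: 15.0, _HD: 20.0, _M: 22.0},
    ("aboveground_dry_weight", "plant"): {_T: 6.0, _HD: 25.0, _M: 42.0},
    ("root_dry_weight", "plant"): {_T: 2.0, _HD: 6.0, _M: 8.0},
    ("tiller_number", "plant"): {_T: 12.0, _HD: 14.0, _M: 14.0},
    ("panicle_emergence", "plant"): {_T: 4.0, _HD: 10.0, _M: 12.0},
    ("MDA", "root"): {_T: 18.0, _HD: 22.0, _M: 25.0},
    ("MDA", "stem"): {_T: 12.0, _HD: 15.0, _M: 18.0},
    ("MDA", "leaf"): {_T: 28.0, _HD: 32.0, _M: 35.0},
    ("SOD", "root"): {_T: 180.0, _HD: 210.0, _M: 230.0},
    ("Glu", "rhizosphere"): {_T: 9.0, _HD: 11.0, _M: 13.0},
}
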