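"""Synthetic soil-rice datasets with the statistical structure the analysis
assumes.

The generator emulates a pot experiment around a Pb-Zn mining site: a
contaminated and a control plot, four replicate pots per group, six metals,
and tissue concentrations produced by a forward transfer model — soil
concentrations drawn from a moment-matched lognormal, then

    root  = soil * BF_root/soil * eps
    stem  = root * TF_stem/root * eps
    leaf  = stem * TF_leaf/stem * eps
    grain = stem * TF_grain/stem * eps   (heading and maturity only)

where each eps is an independent unit-mean lognormal noise factor
exp(N(-sigma^2/2, sigma^2)), so replicate-wise ratio estimators of the
factors are unbiased.  Growth/biochemical endpoints are generated as the
control mean times (1 + effect/100) times the same style of noise.  A
truth record keeps every generating value, and the whole dataset is
reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import defaults
from .core_data import Group, Metal, MetalConcentrationTable, Stage, Tissue
from .phytotox import EndpointTable

_CHAIN: Tuple[Tuple[Tissue, Tissue, str], ...] = (
    (Tissue.ROOT, Tissue.SOIL, "BF_root_soil"),
    (Tissue.STEM, Tissue.ROOT, "TF_stem_root"),
    (Tissue.LEAF, Tissue.STEM, "TF_leaf_stem"),
    (Tissue.GRAIN, Tissue.STEM, "TF_grain_stem"),
)


class GeneratorConfig(BaseModel):
    """Generating parameters; defaults reproduce the study conditions.

    ``soil_cv`` may be a single coefficient of variation or a per-metal map;
    the default is the per-metal replicate CV of the contaminated plot.
    ``tissue_noise_sd`` is the log-scale sigma of the multiplicative noise
    on each transfer step.  ``endpoint_cv`` is the replicate CV of endpoint
    measurements.
    """

    model_config = ConfigDict(frozen=True)

    soil_means: Dict[Metal, float] = Field(
        default_factory=lambda: dict(defaults.SOIL_MEANS_CONTAMINATED))
    control_soil_means: Dict[Metal, float] = Field(
        default_factory=lambda: dict(defaults.SOIL_MEANS_CONTROL))
    soil_cv: Optional[object] = None  # float, per-metal dict, or None for study CVs
    true_factors: Dict[Metal, Dict[Stage, Dict[str, float]]] = Field(
        default_factory=lambda: defaults.TRUE_FACTORS_DEFAULT)
    tissue_noise_sd: float = Field(default=0.1, ge=0)
    n_replicates: int = Field(default=4, ge=1)
    endpoint_effects: Dict[tuple, Dict[Stage, float]] = Field(
        default_factory=lambda: defaults.ENDPOINT_EFFECTS_DEFAULT)
    endpoint_control_means: Dict[tuple, Dict[Stage, float]] = Field(
        default_factory=lambda: defaults.ENDPOINT_CONTROL_MEANS)
    endpoint_cv: float = Field(default=0.05, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for name, means in (("soil_means", self.soil_means),
                            ("control_soil_means", self.control_soil_means)):
            for m, v in means.items():
                if not v > 0:
                    raise ValueError(f"{name}[{Metal(m).value}] must be > 0, got {v}")
        return self

    def cv_for(self, metal: Metal) -> float:
        if self.soil_cv is None:
            return defaults.SOIL_SD_CONTAMINATED[metal] / defaults.SOIL_MEANS_CONTAMINATED[metal]
        if isinstance(self.soil_cv, dict):
            return float(self.soil_cv[metal])
        return float(self.soil_cv)


@dataclass(frozen=True)
class SyntheticDataset:
    soil: MetalConcentrationTable
    tissue: MetalConcentrationTable
    endpoints: EndpointTable
    truth: dict


def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal draws with E = mean and SD = cv * mean (point mass if cv=0)."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def _unit_noise(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise exp(N(-sigma^2/2, sigma^2))."""
    if sigma == 0:
        return np.ones(n)
    return rng.lognormal(-sigma * sigma / 2.0, sigma, n)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate (soil, tissue, endpoint) tables plus the truth record."""
    rng = np.random.default_rng(config.seed)
    n = config.n_replicates
    sigma = config.tissue_noise_sd

    soil_rows = []
    tissue_rows = []
    # per (group, sample, metal) soil concentration, reused across stages
    soil_conc: Dict[Tuple[Group, str, Metal], float] = {}
    for group, means in ((Group.CONTAMINATED, config.soil_means),
                         (Group.CONTROL, config.control_soil_means)):
        for metal in Metal:
            if metal not in means:
                continue
            draws = _lognormal_mean_cv(rng, means[metal], config.cv_for(metal), n)
            for i, c in enumerate(draws):
                sid = f"{group.value}-{i + 1}"
                soil_conc[(group, sid, metal)] = float(c)
                soil_rows.append(dict(sample_id=sid, group=group.value,
                                      metal=metal.value, concentration=float(c)))

    for group in (Group.CONTAMINATED, Group.CONTROL):
        for metal in Metal:
            factors = config.true_factors.get(metal)
            if factors is None:
                continue
            for stage in Stage:
                stage_factors = factors.get(stage)
                if stage_factors is None:
                    continue
                for i in range(n):
                    sid = f"{group.value}-{i + 1}"
                    upstream = {Tissue.SOIL: soil_conc[(group, sid, metal)]}
                    for tis, parent, kind in _CHAIN:
                        f = stage_factors.get(kind)
                        if f is None:
                            continue  # grain does not exist at tillering
                        eps = float(_unit_noise(rng, sigma, 1)[0])
                        c = upstream[parent] * f * eps
                        upstream[tis] = c
                        tissue_rows.append(
                            dict(sample_id=sid, group=group.value, stage=stage.value,
                                 tissue=tis.value, metal=metal.value, concentration=c)
                        )

    endpoint_rows = []
    for (endpoint, tissue_label), per_stage in config.endpoint_effects.items():
        control_means = config.endpoint_control_means.get((endpoint, tissue_label), {})
        for stage, effect in per_stage.items():
            cm = control_means.get(stage)
            if cm is None:
                raise ValueError(f"no control mean for endpoint {endpoint!r} at {Stage(stage).value}")
            tm = cm * (1.0 + effect / 100.0)
            for group, mean in ((Group.CONTROL, cm), (Group.CONTAMINATED, tm)):
                noise = _unit_noise(rng, _cv_to_sigma(config.endpoint_cv), n)
                for i in range(n):
                    endpoint_rows.append(
                        dict(endpoint=endpoint, stage=Stage(stage).value,
                             tissue=tissue_label, group=group.value,
                             value=mean * float(noise[i]))
                    )

    truth = dict(
        seed=config.seed,
        soil_means={m.value: v for m, v in config.soil_means.items()},
        control_soil_means={m.value: v for m, v in config.control_soil_means.items()},
        soil_cv={m.value: config.cv_for(m) for m in config.soil_means},
        tissue_noise_sd=sigma,
        n_replicates=n,
        true_factors={
            m.value: {s.value: dict(kinds) for s, kinds in per_stage.items()}
            for m, per_stage in config.true_factors.items()
        },
        endpoint_effects={
            f"{e}|{t}": {Stage(s).value: eff for s, eff in per_stage.items()}
            for (e, t), per_stage in config.endpoint_effects.items()
        },
    )

    return SyntheticDataset(
        soil=MetalConcentrationTable(
            pd.DataFrame(soil_rows, columns=["sample_id", "group", "metal", "concentration"]),
            kind="soil"),
        tissue=MetalConcentrationTable(
            pd.DataFrame(tissue_rows, columns=["sample_id", "group", "stage", "tissue", "metal", "concentration"]),
            kind="tissue"),
        endpoints=EndpointTable(
            pd.DataFrame(endpoint_rows, columns=["endpoint", "stage", "tissue", "group", "value"])),
        truth=truth,
    )


def _cv_to_sigma(cv: float) -> float:
    """Log-scale sigma of a unit-mean lognormal with the given CV."""
    if cv == 0:
        return 0.0
    return math.sqrt(math.log(1.0 + cv * cv))
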