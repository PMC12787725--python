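"""Run configuration: packaged defaults plus YAML overrides.

A run is fully described by a :class:`RunConfig`: the screening-standard
set, toxic response factors, exposure parameters per population, RfD/SF
tables, the synthetic-generator settings, Monte Carlo distribution specs
and classification bands.  Every field has a packaged default and can be
overridden from a single YAML file; reports always echo the screening set
actually used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import yaml

from . import defaults
from .core_data import (
    ExposureParameterSet,
    Metal,
    Pathway,
    ScreeningStandardSet,
    ToxicResponseFactorSet,
    ToxicologyReferenceSet,
    parse_metal,
)
from .montecarlo import DistributionSpec
from .pollution import DEFAULT_BANDS, BandTable
from .synthetic import GeneratorConfig


def default_mc_dists(
    exposures: Mapping[str, ExposureParameterSet],
    soil_means: Mapping[Metal, float],
    soil_cv: Mapping[Metal, float],
) -> Dict[str, DistributionSpec]:
    """Package-default uncertainty model: lognormal soil concentrations
    (moment-matched to the replicate mean and CV) and normal intake rates /
    body weight plus uniform exposure duration per population, each
    truncated to physical ranges."""
    dists: Dict[str, DistributionSpec] = {}
    for m, mean in soil_means.items():
        dists[f"c_soil.{Metal(m).value}"] = DistributionSpec.lognormal_from_mean_cv(
            mean, max(soil_cv[m], 1e-6)
        )
    for pop, p in exposures.items():
        dists[f"{pop}.IngR"] = DistributionSpec.normal(p.IngR, 0.2 * p.IngR, lower=0.0)
        dists[f"{pop}.InhR"] = DistributionSpec.normal(p.InhR, 0.2 * p.InhR, lower=0.0)
        dists[f"{pop}.BW"] = DistributionSpec.normal(p.BW, 0.1 * p.BW, lower=0.3 * p.BW)
        dists[f"{pop}.ED"] = DistributionSpec(
            family="uniform", low=0.75 * p.ED, high=1.25 * p.ED
        )
    return dists


@dataclass
class RunConfig:
    screening: ScreeningStandardSet = dc_field(
        default_factory=lambda: defaults.STUDY_BACKCALCULATED)
    tox: ToxicResponseFactorSet = dc_field(
        default_factory=lambda: defaults.TOXIC_RESPONSE_DEFAULT)
    exposures: Dict[str, ExposureParameterSet] = dc_field(
        default_factory=lambda: dict(defaults.EXPOSURE_DEFAULTS))
    toxref: ToxicologyReferenceSet = dc_field(
        default_factory=lambda: defaults.TOXREF_DEFAULT)
    generator: GeneratorConfig = dc_field(default_factory=GeneratorConfig)
    mc_n: int = 10_000
    mc_dists: Optional[Dict[str, DistributionSpec]] = None
    bands: Mapping[str, BandTable] = dc_field(default_factory=lambda: DEFAULT_BANDS)

    def resolved_mc_dists(self) -> Dict[str, DistributionSpec]:
        if self.mc_dists is not None:
            return self.mc_dists
        return default_mc_dists(
            self.exposures,
            self.generator.soil_means,
            {m: self.generator.cv_for(m) for m in self.generator.soil_means},
        )

    def canonical_dict(self) -> dict:
        """Stable, JSON-serialisable view used for hashing and the manifest."""
        return dict(
            screening=dict(
                values={m.value: v for m, v in self.screening.values.items()},
                provenance=self.screening.provenance,
            ),
            tox={m.value: v for m, v in self.tox.values.items()},
            exposures={
                pop: p.model_dump(exclude={"population"})
                for pop, p in sorted(self.exposures.items())
            },
            toxref=dict(
                rfd={m.value: {p.value: v for p, v in d.items()}
                     for m, d in self.toxref.rfd.items()},
                sf={m.value: {p.value: v for p, v in d.items()}
                    for m, d in self.toxref.sf.items()},
            ),
            generator=dict(
                soil_means={m.value: v for m, v in self.generator.soil_means.items()},
                control_soil_means={m.value: v
                                    for m, v in self.generator.control_soil_means.items()},
                soil_cv={m.value: self.generator.cv_for(m)
                         for m in self.generator.soil_means},
                tissue_noise_sd=self.generator.tissue_noise_sd,
                n_replicates=self.generator.n_replicates,
                endpoint_cv=self.generator.endpoint_cv,
                seed=self.generator.seed,
            ),
            mc_n=self.mc_n,
            mc_dists={k: v.model_dump(exclude_none=True)
                      for k, v in sorted(self.resolved_mc_dists().items())},
            bands={k: [[lo, hi, lab] for lo, hi, lab in v]
                   for k, v in self.bands.items()},
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _metal_map(d: Mapping[str, float]) -> Dict[Metal, float]:
    return {parse_metal(k): float(v) for k, v in d.items()}


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Build a RunConfig from packaged defaults, overridden by a YAML file.

    Recognised top-level sections: ``screening`` (either ``set: <name>``
    choosing a packaged set, or explicit ``values``/``provenance``),
    ``tox_factors``, ``exposures`` (per population, partial overrides),
    ``toxref`` (``rfd``/``sf`` nested metal -> pathway maps, full
    replacement per metal), ``generator``, ``montecarlo`` (``n`` and
    ``distributions``) and ``bands``.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    if "screening" in raw:
        sc = raw["screening"]
        if "set" in sc:
            name = sc["set"]
            if name not in defaults.SCREENING_SETS:
                raise KeyError(
                    f"unknown screening set {name!r}; available: "
                    f"{sorted(defaults.SCREENING_SETS)}"
                )
            cfg.screening = defaults.SCREENING_SETS[name]
        else:
            cfg.screening = ScreeningStandardSet(
                values=_metal_map(sc.get("values", {})),
                provenance=sc.get("provenance", "user-supplied"),
            )
    if "tox_factors" in raw:
        merged = dict(cfg.tox.values)
        merged.update(_metal_map(raw["tox_factors"]))
        cfg.tox = ToxicResponseFactorSet(values=merged)
    if "exposures" in raw:
        for pop, overrides in raw["exposures"].items():
            base = cfg.exposures.get(pop)
            data = base.model_dump() if base else {"population": pop}
            data.update(overrides)
            cfg.exposures[pop] = ExposureParameterSet(**data)
    if "toxref" in raw:
        tr = raw["toxref"]
        rfd = {m: dict(d) for m, d in cfg.toxref.rfd.items()}
        sf = {m: dict(d) for m, d in cfg.toxref.sf.items()}
        for section, target in (("rfd", rfd), ("sf", sf)):
            for msym, per_path in (tr.get(section) or {}).items():
                target[parse_metal(msym)] = {
                    Pathway(p): float(v) for p, v in per_path.items()
                }
        cfg.toxref = ToxicologyReferenceSet(rfd=rfd, sf=sf,
                                            provenance=cfg.toxref.provenance)
    if "generator" in raw:
        g = raw["generator"]
        data = {}
        if "soil_means" in g:
            data["soil_means"] = _metal_map(g["soil_means"])
        if "control_soil_means" in g:
            data["control_soil_means"] = _metal_map(g["control_soil_means"])
        for key in ("soil_cv", "tissue_noise_sd", "n_replicates", "endpoint_cv", "seed"):
            if key in g:
                data[key] = g[key]
        base = cfg.generator.model_dump()
        base.update(data)
        cfg.generator = GeneratorConfig(**base)
    if "montecarlo" in raw:
        mc = raw["montecarlo"]
        if "n" in mc:
            cfg.mc_n = int(mc["n"])
        if "distributions" in mc:
            cfg.mc_dists = {
                k: DistributionSpec(**v) for k, v in mc["distributions"].items()
            }
    if "bands" in raw:
        bands = dict(cfg.bands)
        for scheme, rows in raw["bands"].items():
            bands[scheme] = tuple(
                (float(lo), float("inf") if hi in (None, "inf") else float(hi), str(lab))
                for lo, hi, lab in rows
            )
        cfg.bands = bands
    return cfg
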