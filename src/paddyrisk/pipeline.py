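"""End-to-end orchestration: generate (or load) data, run every assessment
stage, write CSV reports and a run manifest."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from . import __version__
from .accumulation import transfer_table
from .config import RunConfig
from .core_data import (
    Group,
    MetalConcentrationTable,
    Stage,
    Tissue,
    validate_parameter_sets,
)
from .health import compute_risk_table
from .montecarlo import simulate
from .phytotox import EndpointTable, endpoint_summary
from .pollution import assess_soil
from .synthetic import GeneratorConfig, generate


class PipelineConfigError(RuntimeError):
    """Raised when the parameter sets cannot support an end-to-end run."""

    def __init__(self, report):
        self.report = report
        super().__init__(str(report))


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str
    timestamp: str
    outputs: Dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        lines = [
            f"seed: {self.seed}",
            f"config_hash: {self.config_hash}",
            f"version: {self.version}",
            f"timestamp: {self.timestamp}",
            "outputs:",
        ]
        lines += [f"  {name}: {p}" for name, p in sorted(self.outputs.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: RunConfig,
    out_dir,
    seed: int = 0,
    soil: Optional[MetalConcentrationTable] = None,
    tissue: Optional[MetalConcentrationTable] = None,
    endpoints: Optional[EndpointTable] = None,
) -> RunManifest:
    """Execute accumulation -> indices -> health risk -> Monte Carlo ->
    phytotoxicity on provided tables, generating any that are missing.

    Raises :class:`PipelineConfigError` (before writing anything) if the
    parameter sets are incomplete.
    """
    report = validate_parameter_sets(
        config.screening, config.tox, config.exposures.values(), config.toxref
    )
    if not report.ok:
        raise PipelineConfigError(report)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}

    if soil is None or tissue is None or endpoints is None:
        gen_cfg = GeneratorConfig(**{**config.generator.model_dump(), "seed": seed})
        dataset = generate(gen_cfg)
        soil = soil or dataset.soil
        tissue = tissue or dataset.tissue
        endpoints = endpoints or dataset.endpoints
        soil.to_csv(out / "soil.csv")
        tissue.to_csv(out / "tissue.csv")
        endpoints.to_csv(out / "endpoints.csv")
        (out / "truth.json").write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
        outputs.update(soil="soil.csv", tissue="tissue.csv",
                       endpoints="endpoints.csv", truth="truth.json")

    contaminated_soil = soil.subset(group=Group.CONTAMINATED)
    contaminated_tissue = tissue.subset(group=Group.CONTAMINATED)

    factors = transfer_table(contaminated_tissue, contaminated_soil)
    factors.to_csv(out / "transfer_factors.csv")
    outputs["transfer_factors"] = "transfer_factors.csv"

    soil_means = contaminated_soil.mean_by_metal()
    indices = assess_soil(soil_means, config.screening, config.tox, config.bands)
    indices.to_frame().to_csv(out / "pollution_indices.csv", index=False)
    (out / "pollution_summary.txt").write_text(indices.summary_line() + "\n")
    outputs["pollution_indices"] = "pollution_indices.csv"
    outputs["pollution_summary"] = "pollution_summary.txt"

    grain = contaminated_tissue.subset(stage=Stage.MATURITY, tissue=Tissue.GRAIN)
    c_rice = grain.mean_by_metal()
    risk = compute_risk_table(c_rice, soil_means, config.exposures, config.toxref)
    risk.to_csv(out / "health_risk.csv")
    outputs["health_risk"] = "health_risk.csv"

    mc = simulate(
        c_rice, soil_means, config.exposures, config.toxref,
        config.resolved_mc_dists(), n=config.mc_n, seed=seed,
    )
    mc.frame.to_csv(out / "montecarlo.csv", index=False)
    outputs["montecarlo"] = "montecarlo.csv"

    summary = endpoint_summary(endpoints)
    summary.to_csv(out / "phytotox_summary.csv", index=False)
    outputs["phytotox_summary"] = "phytotox_summary.csv"

    manifest = RunManifest(
        seed=seed,
        config_hash=config.config_hash(),
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=outputs,
    )
    manifest.write(out / "manifest.txt")
    return manifest
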