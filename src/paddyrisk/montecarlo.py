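"""Monte Carlo propagation of parameter uncertainty through the health-risk
model.

Each uncertain input (a soil or grain concentration, an intake rate, body
weight, exposure duration) gets a univariate distribution; every iteration
draws one value per uncertain input, pushes it through the exact same
intake/HQ/CR arithmetic as the deterministic pipeline, and the result is
summarised as exceedance probabilities (HQ/HI > 1, CR/TCR > 1e-4) and
percentiles per endpoint.  Inputs are sampled independently; point
distributions reduce the simulation to the deterministic pipeline
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import SimpleNamespace
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .core_data import (
    METAL_ORDER,
    Metal,
    Pathway,
    PATHWAY_ORDER,
    ExposureParameterSet,
    ToxicologyReferenceSet,
)
from .health import (
    CR_UNACCEPTABLE,
    HQ_THRESHOLD,
    adi_food,
    adi_soil,
    hazard_quotient,
)

_FAMILIES = ("point", "normal", "lognormal", "triangular", "uniform")

#: exposure-parameter names that may be given a distribution
_VARIABLE_EXPOSURE = ("IR", "IngR", "InhR", "BW", "ED")


class DistributionSpec(BaseModel):
    """A named univariate distribution with optional truncation bounds.

    Families and their parameters:
      point(value); normal(mean, sd); lognormal(mu, sigma) on the log scale;
      triangular(low, mode, high); uniform(low, high).
    Truncation (``lower``/``upper``) is applied by rejection sampling.
    """

    model_config = ConfigDict(frozen=True)

    family: str
    value: Optional[float] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    mu: Optional[float] = None
    sigma: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    mode: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        f = self.family
        if f not in _FAMILIES:
            raise ValueError(f"unknown distribution family {f!r}; expected one of {_FAMILIES}")
        need = {
            "point": ("value",),
            "normal": ("mean", "sd"),
            "lognormal": ("mu", "sigma"),
            "triangular": ("low", "mode", "high"),
            "uniform": ("low", "high"),
        }[f]
        for name in need:
            if getattr(self, name) is None:
                raise ValueError(f"{f} distribution requires parameter {name!r}")
        if f == "normal" and self.sd <= 0:
            raise ValueError(f"normal sd must be > 0, got {self.sd}")
        if f == "lognormal" and self.sigma <= 0:
            raise ValueError(f"lognormal sigma must be > 0, got {self.sigma}")
        if f == "triangular" and not (self.low <= self.mode <= self.high and self.low < self.high):
            raise ValueError("triangular requires low <= mode <= high and low < high")
        if f == "uniform" and not self.low < self.high:
            raise ValueError("uniform requires low < high")
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise ValueError("empty truncation interval")
        return self

    # -- convenience constructors ------------------------------------------

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls(family="point", value=value)

    @classmethod
    def normal(cls, mean: float, sd: float, lower: Optional[float] = None,
               upper: Optional[float] = None) -> "DistributionSpec":
        return cls(family="normal", mean=mean, sd=sd, lower=lower, upper=upper)

    @classmethod
    def lognormal_from_mean_cv(cls, mean: float, cv: float,
                               lower: Optional[float] = None,
                               upper: Optional[float] = None) -> "DistributionSpec":
        """Moment-matched lognormal: E[X] = mean, SD[X] = cv * mean."""
        if mean <= 0 or cv <= 0:
            raise ValueError("mean and cv must be > 0")
        sigma2 = math.log(1.0 + cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        return cls(family="lognormal", mu=mu, sigma=math.sqrt(sigma2),
                   lower=lower, upper=upper)


def sample(spec: DistributionSpec, n: int,
           rng: Union[int, np.random.Generator]) -> np.ndarray:
    """Draw ``n`` values; reproducible given (spec, n, seed).

    Truncation is enforced by rejection; if the bounds exclude essentially
    all mass (acceptance rate below 1e-4) a ValueError is raised.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if spec.family == "point":
        out = np.full(n, float(spec.value))
        _check_bounds(out, spec)
        return out

    def draw(k: int) -> np.ndarray:
        if spec.family == "normal":
            return rng.normal(spec.mean, spec.sd, k)
        if spec.family == "lognormal":
            return rng.lognormal(spec.mu, spec.sigma, k)
        if spec.family == "triangular":
            return rng.triangular(spec.low, spec.mode, spec.high, k)
        return rng.uniform(spec.low, spec.high, k)

    if spec.lower is None and spec.upper is None:
        return draw(n)

    accepted: list = []
    total = 0
    got = 0
    while got < n:
        batch = draw(max(n, 1000))
        total += batch.size
        keep = np.ones(batch.size, dtype=bool)
        if spec.lower is not None:
            keep &= batch >= spec.lower
        if spec.upper is not None:
            keep &= batch <= spec.upper
        kept = batch[keep]
        accepted.append(kept)
        got += kept.size
        if total >= 1_000_000 and got / total < 1e-4:
            raise ValueError(
                f"truncation bounds [{spec.lower}, {spec.upper}] exclude nearly all "
                f"mass of the {spec.family} distribution (acceptance {got/total:.2e})"
            )
    return np.concatenate(accepted)[:n]


def _check_bounds(values: np.ndarray, spec: DistributionSpec) -> None:
    if spec.lower is not None and np.any(values < spec.lower):
        raise ValueError(f"point value {spec.value} below truncation lower bound {spec.lower}")
    if spec.upper is not None and np.any(values > spec.upper):
        raise ValueError(f"point value {spec.value} above truncation upper bound {spec.upper}")


@dataclass(frozen=True)
class SimulationResult:
    """Summary of one Monte Carlo run.

    ``frame`` has one row per (population, endpoint) with the exceedance
    probability and the mean/p5/p50/p95 of the endpoint's distribution;
    ``draws`` optionally keeps the raw per-iteration arrays for audit.
    """

    n_iter: int
    seed: int
    frame: pd.DataFrame
    draws: Optional[Dict[str, np.ndarray]] = None

    def exceedance(self, population: str, endpoint: str) -> float:
        df = self.frame
        row = df[(df["population"] == population) & (df["endpoint"] == endpoint)]
        if row.empty:
            raise KeyError(f"no endpoint {endpoint!r} for population {population!r}")
        return float(row["exceedance"].iloc[0])


def _valid_keys(
    c_rice: Mapping[Metal, float],
    c_soil: Mapping[Metal, float],
    exposures: Mapping[str, ExposureParameterSet],
) -> set:
    keys = set()
    for m in c_rice:
        keys.add(f"c_rice.{Metal(m).value}")
    for m in c_soil:
        keys.add(f"c_soil.{Metal(m).value}")
    for pop in exposures:
        for name in _VARIABLE_EXPOSURE:
            keys.add(f"{pop}.{name}")
    return keys


def simulate(
    c_rice: Mapping[Metal, float],
    c_soil: Mapping[Metal, float],
    exposures: Mapping[str, ExposureParameterSet],
    toxref: ToxicologyReferenceSet,
    dist_config: Mapping[str, DistributionSpec],
    n: int = 10_000,
    seed: int = 0,
    metals: Sequence[Metal] = METAL_ORDER,
    keep_draws: bool = False,
) -> SimulationResult:
    """Propagate the configured uncertainties through the risk model.

    ``dist_config`` keys name the uncertain input: ``c_soil.Pb``,
    ``c_rice.Cd``, ``adult.BW``, ``child.IngR`` ...; any input without a
    spec keeps its fixed value from ``c_rice``/``c_soil``/``exposures``.
    When a population's ED is drawn, its non-carcinogenic averaging time
    follows as ED*365 (the carcinogenic averaging time stays at the fixed
    lifetime value).  Unknown keys raise a validation error naming them.
    """
    valid = _valid_keys(c_rice, c_soil, exposures)
    unknown = sorted(set(dist_config) - valid)
    if unknown:
        raise ValueError(f"unknown Monte Carlo parameter(s): {', '.join(unknown)}")

    rng = np.random.default_rng(seed)
    # deterministic sampling order: sorted keys
    draws_in: Dict[str, np.ndarray] = {
        key: sample(dist_config[key], n, rng) for key in sorted(dist_config)
    }

    def conc(kind: str, fixed: Mapping[Metal, float], m: Metal):
        return draws_in.get(f"{kind}.{m.value}", float(fixed[m]))

    rows = []
    raw: Dict[str, np.ndarray] = {}
    for pop, base in exposures.items():
        params = {f: getattr(base, f) for f in (
            "IR", "IngR", "InhR", "EF", "ED", "BW", "AT_nc", "AT_ca",
            "SA", "AF", "ABS", "PEF")}
        for name in _VARIABLE_EXPOSURE:
            key = f"{pop}.{name}"
            if key in draws_in:
                params[name] = draws_in[key]
        if f"{pop}.ED" in draws_in:
            params["AT_nc"] = params["ED"] * 365.0
        p = SimpleNamespace(population=pop, **params)

        hi = 0.0
        tcr = 0.0
        endpoint_rows = []
        for m in metals:
            hq_total = 0.0
            cr_total = None
            for path in PATHWAY_ORDER:
                if path == Pathway.FOOD:
                    adi_nc = adi_food(conc("c_rice", c_rice, m), p, "nc")
                    adi_ca = adi_food(conc("c_rice", c_rice, m), p, "ca")
                else:
                    adi_nc = adi_soil(conc("c_soil", c_soil, m), p, path, "nc")
                    adi_ca = adi_soil(conc("c_soil", c_soil, m), p, path, "ca")
                hq_total = hq_total + hazard_quotient(adi_nc, toxref.get_rfd(m, path))
                sf = toxref.get_sf(m, path)
                if sf is not None:
                    cr = adi_ca * sf
                    cr_total = cr if cr_total is None else cr_total + cr
            hi = hi + hq_total
            endpoint_rows.append((f"HQ_{m.value}", hq_total, HQ_THRESHOLD))
            if cr_total is not None:
                tcr = tcr + cr_total
                endpoint_rows.append((f"CR_{m.value}", cr_total, CR_UNACCEPTABLE))
        endpoint_rows.append(("HI", hi, HQ_THRESHOLD))
        endpoint_rows.append(("TCR", tcr, CR_UNACCEPTABLE))

        for name, values, threshold in endpoint_rows:
            arr = np.broadcast_to(np.asarray(values, dtype=float), (n,))
            rows.append(
                dict(
                    population=pop,
                    endpoint=name,
                    exceedance=float(np.count_nonzero(arr > threshold)) / n,
                    mean=float(arr.mean()),
                    p5=float(np.percentile(arr, 5)),
                    p50=float(np.percentile(arr, 50)),
                    p95=float(np.percentile(arr, 95)),
                )
            )
            if keep_draws:
                raw[f"{pop}.{name}"] = np.array(arr, copy=True)

    frame = pd.DataFrame(rows)
    return SimulationResult(n_iter=n, seed=seed, frame=frame,
                            draws=raw if keep_draws else None)
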