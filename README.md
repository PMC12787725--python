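# paddyrisk

Heavy-metal contamination of paddy soils around mining and smelting sites
ends up in rice, and from rice and soil in people. `paddyrisk` is a Python
toolkit for the full assessment chain used in soil–rice studies of Cu, Cr,
Zn, Cd, Pb and As:

- **soil-to-plant transfer** — bioconcentration factors
  (BF<sub>root/soil</sub> = C<sub>root</sub>/C<sub>soil</sub>) and
  translocation factors (TF<sub>stem/root</sub>, TF<sub>leaf/stem</sub>,
  TF<sub>grain/stem</sub>) per metal and rice growth stage (tillering,
  heading, maturity);
- **soil pollution and ecological risk** — single-metal pollution index
  PI = C<sub>i</sub>/S<sub>i</sub> against regulatory screening values, the
  Nemerow composite NIPI = √((PI̅² + PI²<sub>max</sub>)/2), and the Hakanson
  indices EI = T<sub>i</sub>·PI and RI = ΣEI, with class labels;
- **human health risk** — four-pathway average daily intake (rice
  consumption, soil ingestion, inhalation, dermal contact), hazard
  quotients HQ = ADI/RfD with HI = ΣHQ, and carcinogenic risk
  CR = ADI·SF with TCR = ΣCR, for adults and children;
- **Monte Carlo uncertainty propagation** — distributions on
  concentrations, intake rates, body weight and exposure duration pushed
  through the identical risk arithmetic, summarised as exceedance
  probabilities P(HI > 1), P(TCR > 10⁻⁴) and percentiles;
- **phytotoxicity endpoints** — percent change of growth, oxidative-stress
  and rhizosphere amino-acid measures in contaminated vs control plants;
- **a synthetic-data generator** that emulates a contaminated/control pot
  experiment through a forward transfer model, so the whole pipeline is
  testable without field data.

It is aimed at environmental and exposure scientists who want these
standard indices computed reproducibly from CSV tables, with every
parameter (screening standards, toxic response factors, exposure constants,
RfD/SF) as explicit, overridable configuration.

## Worked example

```python
import paddyrisk as pr
from paddyrisk import defaults

result = pr.assess_soil(
    defaults.SOIL_MEANS_CONTAMINATED,     # mg/kg DW soil means
    defaults.STUDY_BACKCALCULATED,        # screening values S_i
    defaults.TOXIC_RESPONSE_DEFAULT,      # Hakanson T_i
)
print(result.summary_line())
print(result.to_frame().round(2))
```

prints

```
NIPI=4.64 (high); RI=188.90 (moderate); screening set: synthetic: back-calculated from site mean concentrations and published PI values
  metal    pi    pi_class      ei      ei_class
0    Cu  0.65  unpolluted    3.26           low
1    Cr  0.32  unpolluted    0.64           low
2    Zn  1.96         low    1.96           low
3    Cd  3.35        high  100.50  considerable
4    Pb  4.66        high   23.30           low
5    As  5.92        high   59.24      moderate
```

i.e. the soils are high-pollution overall (NIPI > 3, driven by As, Pb and
Cd), and the integrated ecological risk is moderate (150 ≤ RI < 300) with
Cd the dominant contributor through its toxic response factor of 30.

An entire run — synthetic data generation, transfer factors, indices,
health risk, Monte Carlo, phytotoxicity — from the shell:

```sh
paddyrisk run-all --seed 1 --out results/demo
```

writes per-stage CSVs plus a manifest with the config hash and seed.
Individual stages are available as `generate`, `factors`, `indices`,
`health-risk`, `montecarlo` and `phytotox` subcommands operating on CSV
files.

## Layout

```
src/paddyrisk/
  core_data.py     domain types, CSV IO, parameter sets, validation
  defaults.py      packaged parameter tables (explicit, overridable config)
  accumulation.py  BF/TF computation, ranking
  pollution.py     PI, NIPI, EI, RI and classification bands
  health.py        ADI/HQ/HI/CR/TCR and the wide risk-table layout
  montecarlo.py    distribution specs, sampling, uncertainty propagation
  phytotox.py      percent-change endpoint summaries
  synthetic.py     forward-model data generator with truth records
  config.py        YAML configuration on top of the defaults
  pipeline.py      run orchestration and manifest
  cli.py           click command-line interface
```

See `docs/methods.md` for the model descriptions, parameter provenance and
known limitations.
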