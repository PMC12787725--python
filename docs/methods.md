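# Methods

## Scope and data model

The package assesses six metals (Cu, Cr, Zn, Cd, Pb, As) in a soil–rice
system. All concentrations are mg/kg dry weight end to end; there is no
unit conversion anywhere in the pipeline. Concentration tables are keyed
by (sample, growth stage, tissue, metal) with a contaminated/control group
label; the key is unique, concentrations are non-negative, and grain
records cannot exist at tillering because the grain has not formed yet.
Control-group records flow through every stage unchanged — the only place
the two groups are compared is the phytotoxicity summary.

## Soil-to-plant transfer

Bioconcentration (root/soil) and translocation (stem/root, leaf/stem,
grain/stem) factors are plain concentration ratios. Replicates are
aggregated **ratio-wise**: each pot contributes its own ratio and the
table reports their mean ± SD. The alternative — dividing mean
concentrations — gives slightly different values under multiplicative
noise; the ratio-wise choice matches a per-replicate "value ± SD"
presentation and makes the estimator unbiased under the generator's
unit-mean noise (below). A factor is *absent* (not zero, not NaN-as-number)
exactly when its numerator tissue does not exist at that stage, and the
absence carries a reason string. Rankings sort descending with ties broken
by the fixed metal order (Cu, Cr, Zn, Cd, Pb, As) and flagged.

## Pollution and ecological indices

PI = C/S with screening value S > 0; NIPI = √((PI̅² + PI²max)/2);
EI = T·PI; RI = ΣEI. The Hakanson toxic response factors default to
Cd 30, As 10, Pb 5, Cu 5, Cr 2, Zn 1. Algebraically PImax/√2 ≤ NIPI ≤
PImax, which the property tests assert on random vectors.

Screening standards are always explicit configuration and every report
echoes the set used. Three sets ship with the package: the GB 15618-2018
paddy-field risk screening values for the pH 5.5–6.5 and 6.5–7.5 bands,
and a third, synthetic set back-calculated from the calibration site's
mean soil concentrations and its published pollution indices (Cu 100,
Cr 218, Zn 250, Cd 0.6, Pb 140, As 25 mg/kg). Five of the six
back-calculated values coincide with the GB paddy 6.5–7.5 band; the Cr
value (~218) matches no GB band, so the set is labelled as a
reconstruction rather than a regulatory standard.

Classification bands are config-overridable tables with **half-open
[lower, upper) boundaries** applied uniformly: EI <40 low, 40–80 moderate,
80–160 considerable, 160–320 high, ≥320 very high; RI <150 low, 150–300
moderate, 300–600 considerable, ≥600 very high; PI <1 unpolluted, 1–2 low,
2–3 moderate, ≥3 high; NIPI <0.7 safe, 0.7–1 warning, 1–2 light, 2–3
moderate, ≥3 high. The convention at the exact boundary is arbitrary; the
half-open choice is documented here once and used everywhere.

## Health risk

Average daily intake per pathway (mg/kg body weight/day):

- food: C_rice·IR·EF·ED/(BW·AT)
- soil ingestion: C_soil·IngR·EF·ED/(BW·AT)·10⁻⁶
- inhalation: C_soil·InhR·EF·ED/(PEF·BW·AT)·10⁻⁶
- dermal: C_soil·SA·AF·ABS·EF·ED/(BW·AT)·10⁻⁶

The 10⁻⁶ factor is the mg→kg soil conversion and applies only to the soil
pathways. Non-carcinogenic quotients use AT_nc (ED·365 days by default);
carcinogenic risk averages over a lifetime AT_ca (70·365 days). Keeping
the two averaging times distinct is standard practice and necessary to get
the usual magnitudes out of a single parameter set. HI and TCR are exact
sums over the reported cells; a (metal, pathway) without an established
slope factor contributes no carcinogenic cell at all (defaults: Cu and Zn
have none anywhere, Pb none dermally), and threshold classifications are
strict (HQ/HI > 1 "risk"; CR/TCR > 10⁻⁴ "unacceptable", ≥10⁻⁶
"acceptable", otherwise "no obvious risk") so the boundary value itself is
on the non-risk side.

Exposure constants (adult: IR 0.3 kg/d, IngR 100 mg/d, InhR 14.5 m³/d,
EF 350 d/y, ED 24 y, BW 60 kg, SA 5700 cm², AF 0.07 mg/cm²/d, ABS 0.001,
PEF 1.36×10⁹ m³/kg; child: IR 0.2, IngR 200, InhR 7.5, ED 6, BW 16,
SA 2800, AF 0.2) and the RfD/SF tables follow US EPA IRIS/RSL and Chinese
technical-guideline conventions; they are configuration with provenance
strings, not results, and per-cell HQ/CR values therefore depend entirely
on the table supplied. What the package guarantees — and tests — is the
arithmetic: linearity in concentrations, exact additivity of margins, and
the layout of the wide risk table.

All intake/quotient functions are elementwise, accepting scalars or numpy
arrays; this is what lets the Monte Carlo module reuse them unchanged.

## Monte Carlo

Uncertain inputs are named flatly (`c_soil.Pb`, `c_rice.Cd`, `adult.BW`,
`child.IngR`, …) and each carries a univariate distribution: point,
normal, lognormal (log-scale μ, σ, with a moment-matched mean/CV
constructor), triangular or uniform, with optional truncation enforced by
rejection sampling (an acceptance rate below 10⁻⁴ is an error). Inputs are
sampled independently — no correlation structure is modelled. When a
population's ED is drawn, AT_nc follows as ED·365 while AT_ca stays at the
fixed lifetime. The default is 10,000 iterations; the seed is mandatory in
the CLI.

Draws are fed through the deterministic intake/quotient functions with
sums accumulated in the same order as the deterministic aggregation, so
all-point configurations reproduce the deterministic pipeline bit for bit
(a tested invariant, and the reason sums are sequential rather than
pairwise). Exceedance probabilities are the fraction of iterations above
the threshold; a reported 100% is a sample statement (≥ n/n), not a
certainty claim.

The default uncertainty model (used when no distributions are configured)
puts moment-matched lognormals on soil concentrations (replicate mean and
CV), normals on IngR/InhR (20% CV, truncated at 0) and BW (10% CV), and a
±25% uniform on ED, per population. These are package choices standing in
for study-specific distribution tables.

## Phytotoxicity

Endpoints (plant height, root length, dry weights, tiller and panicle
counts, MDA, SOD/POD/CAT, rhizosphere amino acids) are summarised as
100·(treated − control)/control on group means, negative meaning
inhibition. The replicate spread reported is the SD of per-replicate
percent changes against the control mean. Significance testing
(ANOVA/Tukey) is deliberately out of scope: the report carries replicate
SDs so any external tool can test, and the quantity of interest here is
the descriptive percent change.

## Synthetic-data generator

The generator emulates the calibration pot experiment: two groups
(contaminated/control), four replicate pots, six metals, three stages.

- Soil concentrations are lognormal, **moment-matched** so the arithmetic
  mean and SD equal the configured mean and CV·mean. Defaults are the
  calibration site's contaminated and control means and per-metal
  replicate CVs (e.g. Pb 652.34 ± 29.73 mg/kg, CV ≈ 0.046).
- Tissue concentrations follow the forward chain root = soil·BF·ε,
  stem = root·TF·ε, leaf = stem·TF·ε, grain = stem·TF·ε, with the true
  factors defaulting to the calibration values (e.g. BF_Cd rising from
  0.79 at tillering to 1.95 at maturity) and grain generated only at
  heading and maturity.
- Each ε is an independent **unit-mean** lognormal, exp(N(−σ²/2, σ²)) with
  σ = 0.1 by default. Unit mean makes every replicate-wise ratio estimator
  unbiased, which is what the parameter-recovery tests assert; a plain
  exp(N(0, σ²)) noise would bias ratios upward by exp(σ²/2).
- Endpoints are control mean × (1 + effect/100) × noise with a 5%
  replicate CV; effect defaults are the calibration percent changes
  (growth inhibition 20–60%, MDA up to +116.6% in stems at heading, Glu
  exudation up to +211.8% at maturity) over plausible control anchors.
- A truth record stores every generating value; the dataset is
  bit-reproducible from the seed.

What the generator does **not** emulate: spatial heterogeneity, temporal
soil dynamics, metal speciation and pH-dependent bioavailability,
correlation between metals within a pot, or measurement-protocol error
structure. Passing recovery tests therefore demonstrates that the
estimators are correct under the stated noise model, not that field data
will behave this way.

## Numerical choices

- Full precision everywhere internally; 2-decimal/3-significant-figure
  rounding only at the report layer.
- Ratio and index functions raise on non-positive denominators rather
  than returning infinities.
- Marginal sums accumulate sequentially in a fixed order (pathways within
  metal, metals within population) for bitwise reproducibility.
- CSV reads use round-trip float parsing so write→read is bit-identical.
- Tie-breaks in rankings use the canonical metal order and set a tie flag.

## Problem sizes

The shipped tests run the generator at 2–4 replicates (10⁴ for the
SD-calibration check), 200 seeded datasets for parameter recovery, and
10⁴ Monte Carlo iterations for the distribution-tail checks — enough for
the binomial/CLT error bounds used in the assertions, and the same
iteration count as the default simulation setting.

## Known limitations

- Screening values, exposure constants and RfD/SF tables vary by
  jurisdiction and study; results are only as meaningful as the supplied
  configuration, which is why every report echoes it.
- Carcinogenic totals silently skip absent slope-factor cells; comparing
  TCR across studies requires comparing SF coverage too.
- The Monte Carlo assumes independence across inputs; correlated
  exposures (e.g. body weight vs intake) are not representable.
- Percent-change summaries carry no inferential statistics by design.
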