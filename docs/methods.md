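# Methods

This note documents the model behind `bioref`: the balances, the economic
engine, the calibrated constants and the choices made where the design was
genuinely open. Nothing here states a number the tests or
`scripts/acceptance.py` do not themselves compute.

## Process model

All flows are annual averages (t/yr); no kinetics or scheduling is modelled —
the 40-day batch culture enters only through its yield endpoint and the
fermentation capital block.

**Autohydrolysis.** Dry feed F splits into residual solid F·Y_s (Y_s the
calibrated solid yield) and solubilized mass F·(1−Y_s). The solid leaves at
50 % wet-basis moisture; that water is drawn from the treatment water, so the
liquor carries `lsr·F − Y_s·F` t of water. The monomeric-sugar share of the
solubilized mass is fixed by the calibrated recovery (kg sugar per dry t,
see Calibration). Heating duty is sensible heat of the whole slurry
(F·(1+lsr)) from 25 °C to 180 °C with a constant slurry heat capacity of
4.0 kJ/kg·K — a deliberate simplification standing in for a flash-recovery
heat network.

**Washing.** 3.5 t water per dry t pulp, all of it joining the liquor; sugar
recovery by washing is complete (already folded into the calibrated sugar
recovery). The pulp's moisture is unchanged.

**Evaporation.** Liquor volume is approximated by its water volume at
1 t/m³; solute volume is ignored. Final water = sugar mass / 200 g/L;
steam = evaporated water / steam economy (2.6), converted to MJ with a
constant steam enthalpy of 2244 MJ/t. With the packaged profiles the final
liquor's *total* solute concentration slightly exceeds 200 g/L (byproducts
ride along); the calibration controls sugar *mass*, so this shifts only the
evaporation duty marginally.

**Post-hydrolysis.** Sets the liquor composition to the measured
post-hydrolysis profile (g/L per species) scaled to the stream's sugar mass;
byproduct species are capped at the available non-sugar solute pool so the
stage conserves mass. H₂SO₄ dose = 1 wt % of liquor mass (interpreted as
weight percent, consistent with the 0.5–4 wt % operating envelope); an equal
mass of neutralization agent is recorded as a consumable but not priced
separately (it is part of the waste-treatment charge). Heating is sensible
heat 100 → 121 °C. The acid and salt masses are not added to the process
stream (yield-only accounting).

**Microbial culture.** Total carbon source = sugars/(1−x_ac) with x_ac the
acetate fraction (0 or 0.5); acetate makes up the difference. LA and PHB are
yield fractions of the total carbon source. Cooling energy, 5 MJ per kg of
product, is booked as electricity (the culture runs at 25 °C, so the duty is
chilling/agitation, not steam). Nutrients are dosed per t of carbon source
(see Calibration).

**Recovery.** 100 % recovery of LA and PHB (yield-only accounting; solvent
make-up for CHCl₃ and furfural is lumped into the 1 USD/kg PHB recovery
cost). PHB recovery heat (2 MJ/kg, solvent evaporation) is booked as steam;
LA recovery (8 kWh/kg) as electricity.

**Pyrolysis.** Drying evaporates the solid's moisture (latent heat
2260 kJ/kg); the reactor takes 1.35 MJ per kg dry solid — the midpoint of
the 1.1–1.6 MJ/kg range quoted for slow pyrolysis. The gas product is
credited at 15 MJ/kg, a value chosen so the stated base-case
self-sufficiency (gases covering drying + pyrolysis) holds for both
feedstocks; only the shortfall max(0, demand − credit) would be billed, and
it is zero in all packaged cases. Char/tar/gas/loss fractions must sum to 1.

**Boiler alternative.** Reported alongside every run:
kWh = dry mass × LHV × η / 3.6 with LHV 15 MJ/kg and η = 0.80.

**Conservation.** Every stage records inputs, outputs and declared losses;
`StageResult.mass_closure()` must stay below 10⁻⁶ relative, and property
tests enforce this on arbitrary random configurations.

## Economics

**Capital.** C = C₀(M/M₀)ⁿ per block with installation factor folded into
C₀. Four blocks: feed handling & pretreatment (driven by wet slurry t/yr,
n = 0.7), evaporation (water evaporated, n = 0.8), fermentation & recovery
(sugar throughput, n = 0.8 — sized by liquor throughput, so acetate
enrichment does not change the investment), pyrolysis train (dry solid,
n = 0.6). All exponents sit inside the conventional 0.6–0.8 band.

**Operating cost.** Feedstock, fresh water, steam (10 USD/t), electricity
(85 USD/MWh), H₂SO₄, nutrients, acetate, PHB recovery, labor, maintenance +
property taxes (2 % of TCI), and waste treatment at 1 USD/m³ of total liquid
effluent. The effluent is evaporator condensate + culture broth water, which
by conservation equals all water brought in — this definition keeps the LSR
and wash-water sensitivities physically coherent (more water in ⇒ more water
to treat).

**Cash flow.** Single investment at year 0, constant operation years 1..20,
straight-line depreciation over 10 years, 35 % tax on max(0, revenue − opex −
depreciation) with no loss carry-forward, NPV at 15 %. IRR is found by a
sign-change scan plus Brent's method on (−0.99, 10); it is reported as
undefined when the net flows never change sign. The MSP solver exploits that
NPV is linear and increasing in each product price and brackets the root on
[0, 100] USD/kg (100,000 USD/t for char/tar), tolerance 1000 USD on NPV.

## Calibration (packaged constants that are not public data)

| constant | EUC | SCB | provenance |
|---|---|---|---|
| solid yield Y_s | 0.822 | 0.650 | per-ton char ÷ 0.35 char yield |
| sugar recovery (kg/dry t) | 116.58 | 173.23 | annual LA ÷ 0.31 ÷ 50,000, kept at full precision so the annual product slate reproduces at printed precision |
| culture yields with acetate | 0.07 / 0.09 | same | back-solved from the with-acetate product slate; the nominal 0.31/0.03 reading is inconsistent with it and remains available by override |
| char / tar price | 1500 / 1300 USD/t | same | per-kg interpretation; the literal per-t reading makes the solid line economically irrelevant, contradicting the revenue structure |
| capital C₀ (MM) | 30 / 35 / 32.31 / 15.69 | shared blocks | solved analytically so TCI(EUC) = 113 MM and TCI(SCB) = 146 MM USD exactly |
| labor | 650,000 h/yr × 15 USD/h | same | calibrated so the base-case NPV/IRR pattern lands on the published indicators |
| nutrients | 20 kg / t carbon × 10 USD/kg | same | dose calibrated jointly with labor |
| acetate | 375 USD/t | same | placeholder market estimate; flagged in the config, no silent default |

These are calibrations, not measurements; they are stored in the scenario
YAML files with comments and every one can be overridden per run
(`--set` on the CLI, `set_by_path` in code).

## Sensitivity

One-at-a-time, cloning the config, scaling one numeric leaf by (1 ± 0.20)
and rerunning the entire pipeline. Because capital is recomputed, LSR and
wash-water moves act through three channels: evaporator steam, water +
effluent volume, and evaporator/pretreatment capital — which is what puts
them ahead of a pure steam-price move in the operational case study.
"Raw material availability" scales the annual feed (capacity), not the
feedstock price; with n < 1 scaling, more feed buys capacity at falling unit
cost, making it the strongest operational lever in both directions.

The ±20 %-with-normal-distribution prescription is implemented as two
explicit modes: deterministic endpoints (reproduces the case-study table)
and seeded normal sampling with σ = 10 % of base (±20 % ≈ 2σ), reporting
5th/95th-percentile NPVs. Draws are clipped at zero.

## Synthetic scenarios

`perturb_config` perturbs ~20 listed numeric leaves in three groups
(process σ = 10 %, prices σ = 10 %, yields σ = 5 % by default), clips each
to its validity range and renormalizes dependent constraints (pyrolysis
fractions rescaled to sum 1; sugar recovery capped by solubilized mass;
conversion yields rescaled if their sum exceeds 1). `random_scenario` draws
a composition on the simplex and all parameters from documented plausible
ranges bracketing the two packaged feedstocks (solid yield 0.5–0.9, LSR
4–12, wash 2–5 t/t, combined culture yields ≤ 0.5, feed 10–100 kt/yr).
Both are pure functions of their seed.

What passing the synthetic suites shows: the balances conserve mass, scale
linearly with feed and respect monotonicities across the whole plausible
parameter space. What it does not show: agreement with any real plant —
the generators perturb the model's own parameters and inherit all of its
structural simplifications (no kinetics, 100 % recoveries, constant thermal
properties).

## Numerical choices and degenerate inputs

Liquor already at/above target concentration → warned no-op. Zero feed →
entire liquor line reports zero, economics reduce to fixed costs. Acetate
fraction of 1 is rejected (division by zero), as are non-positive
capacities, yield sums ≠ 1, and solid yields outside (0, 1). IRR tolerance:
|NPV(IRR)| < 1 USD; MSP: |NPV(p*)| < 1000 USD. All validation is collected
into a violation list (field, rule, observed value) rather than failing on
the first error.

## Known limitations

No thermodynamic property package (constant cp, latent heat, steam
enthalpy); no oligomer/monomer speciation beyond the calibrated recovery; no
solvent losses; no working capital, construction interest, inflation or loan
structure; tax without loss carry-forward; absolute economic outputs inherit
the reverse-engineered capital calibration and should be read as a
consistent *pattern* (signs, orderings, relative moves), not as investment
advice. Problem sizes throughout (50,000 t/yr base cases, 100-scenario
property sweeps, 12-sample sensitivity draws) are the package's default
study conditions and keep any full run in the seconds range.
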