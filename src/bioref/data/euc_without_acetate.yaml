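# Packaged base-case scenario.
#
# Calibrated constants (not direct measurements):
#   pretreatment.solid_yield        - dry residual solid fraction after autohydrolysis
#   pretreatment.sugar_recovery_kg_per_ton - monomeric hemicellulosic sugar recovered
#                                     in the post-hydrolyzed liquor per dry t feed
#   economics.capital_blocks        - reference costs reverse-engineered so the four
#                                     base cases land on the intended total capital
#                                     investment; they are NOT vendor quotations
#   economics.prices.acetate_usd_per_t - placeholder market estimate (no surveyed value)
#   economics.prices.char/tar       - interpreted per kg (1500/1300 USD per t); the
#                                     literal per-ton reading is available by override
#   labor hours and nutrient dose   - calibrated operating assumptions
name: euc_without_acetate
feedstock:
  glucans: 0.418
  xylans: 0.107
  arabinans: 0.0
  acetyl_groups: 0.0141
  lignin: 0.323
  extractives: 0.0786
  ash: 0.0059
pretreatment:
  temperature_C: 180.0
  lsr: 6.0
  time_min: 20.0
  wash_water_per_ton_pulp: 3.5
  solid_yield: 0.822
  sugar_recovery_kg_per_ton: 116.58064516129032
liquor_composition:
  cellobiose: 0.0
  glucose: 15.6
  xylose: 153.0
  arabinose: 3.7
  formic_acid: 3.1
  acetic_acid: 12.6
  hmf: 0.2
  furfural: 10.0
target_sugar_conc_gL: 200.0
steam_economy: 2.6
posthydrolysis:
  acid_wt_fraction: 0.01
  temperature_C: 121.0
  time_min: 60.0
conversion:
  alternative: without_acetate
  y_la: 0.31
  y_phb: 0.03
  acetate_fraction_of_carbon: 0.0
  culture_temp_C: 25.0
  culture_days: 40.0
  culture_energy_MJ_per_kg_product: 5.0
recovery:
  phb_recovery_cost_usd_per_kg: 1.0
  phb_recovery_energy_MJ_per_kg: 2.0
  la_recovery_energy_kWh_per_kg: 8.0
pyrolysis:
  char_yield: 0.35
  tar_yield: 0.25
  gas_yield: 0.25
  loss_yield: 0.15
  pyrolysis_energy_MJ_per_kg: 1.35
  gas_self_supply: true
  gas_lhv_MJ_per_kg: 15.0
  feed_moisture: 0.5
  lhv_MJ_per_kg: 15.0
  boiler_efficiency: 0.8
economics:
  annual_feed_t: 50000.0
  prices:
    feedstock_usd_per_t: 7.0
    water_usd_per_m3: 0.7
    electricity_usd_per_mwh: 85.0
    steam_usd_per_t: 10.0
    h2so4_usd_per_kg: 0.09
    nutrients_usd_per_kg: 10.0
    acetate_usd_per_t: 375.0
    waste_treatment_usd_per_m3: 1.0
    char_usd_per_t: 1500.0
    tar_usd_per_t: 1300.0
    phb_usd_per_kg: 6.0
    la_usd_per_kg: 3.5
  labor_rate_usd_per_h: 15.0
  labor_hours_per_year: 650000.0
  maintenance_taxes_fraction_of_tci: 0.02
  income_tax_rate: 0.35
  discount_rate: 0.15
  project_lifetime_years: 20
  depreciation_years: 10
  nutrient_dose_kg_per_t_carbon: 20.0
  capital_blocks:
  - name: feed handling & pretreatment
    co_usd: 30000000.0
    mo: 350000.0
    capacity_key: slurry_t
    n_exponent: 0.7
    installation_factor: 1.0
  - name: evaporation
    co_usd: 35000000.0
    mo: 373604.8387096774
    capacity_key: evaporated_water_t
    n_exponent: 0.8
    installation_factor: 1.0
  - name: fermentation & recovery
    co_usd: 32312676.148765128
    mo: 5829.032258064516
    capacity_key: sugars_t
    n_exponent: 0.8
    installation_factor: 1.0
  - name: pyrolysis train
    co_usd: 15687323.851234872
    mo: 41100.0
    capacity_key: pyrolysis_feed_t
    n_exponent: 0.6
    installation_factor: 1.0
slurry_heat_capacity_kJ_per_kgK: 4.0
steam_enthalpy_MJ_per_t: 2244.0
latent_heat_kJ_per_kg: 2260.0
ambient_temp_C: 25.0
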