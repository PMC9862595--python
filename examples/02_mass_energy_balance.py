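"""Inspect the stage-wise mass and energy balance of one scenario.

Prints the per-stage steam and electricity demands and the pyrolysis /
boiler comparison for the residual solid, on a per-dry-ton basis.
"""

import bioref as br

cfg = br.builtin_scenario("euc_without_acetate")
result = br.run_scenario(cfg)
feed = cfg.economics.annual_feed_t

print(f"scenario: {cfg.name}  ({feed:,.0f} dry t/yr)\n")
print(f"{'stage':<18}{'steam MJ/t':>12}{'electricity kWh/t':>19}")
for name, stage in result.stages.items():
    print(f"{name:<18}{stage.steam_demand_MJ/feed:>12,.0f}"
          f"{stage.electricity_demand_kWh/feed:>19,.1f}")

print(f"\ntotal steam: {result.total_steam_t:,.0f} t/yr "
      f"({result.total_steam_t/feed*1000:,.0f} kg/dry t)")
print(f"total electricity: {result.total_electricity_kWh/1e6:,.1f} GWh/yr")

solid_kg = result.capacities["pyrolysis_feed_t"] / feed * 1000
print(f"\nresidual solid: {solid_kg:,.0f} kg/dry t, either pyrolyzed "
      f"(char {result.products['char']/feed*1000:,.0f} kg/t, "
      f"tar {result.products['tar']/feed*1000:,.0f} kg/t) or burned "
      f"({result.boiler_alternative_kWh/feed:,.0f} kWh/t at 15 MJ/kg, 80% boiler)")
print(
    "\nEvaporation of the dilute liquor to 200 g/L sugars dominates the steam\n"
    "bill; the pyrolysis train itself is energy self-sufficient because the\n"
    "pyrolysis gases cover drying and reactor demand."
)
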