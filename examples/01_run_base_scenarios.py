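"""Run the four packaged biorefinery scenarios and print their product slates.

Each scenario processes 50,000 oven-dry t/yr of feedstock: eucalyptus sawdust
(EUC, LSR 6) or sugarcane bagasse (SCB, LSR 10), with the microbial culture
either fed the plain sugar liquor or enriched with acetate to half the
carbon source.
"""

import bioref as br

print(f"{'scenario':<22}{'LA t/yr':>9}{'PHB t/yr':>10}{'char t/yr':>11}{'tar t/yr':>10}"
      f"{'TCI MM':>8}{'NPV MM':>8}{'IRR %':>7}")
for cfg in br.builtin_scenarios():
    result, econ = br.evaluate(cfg)
    p = result.products
    print(f"{cfg.name:<22}{p['la']:>9,.0f}{p['phb']:>10,.0f}{p['char']:>11,.0f}"
          f"{p['tar']:>10,.0f}{econ.tci_usd/1e6:>8,.0f}{econ.npv_usd/1e6:>8,.1f}"
          f"{(econ.irr or 0)*100:>7,.1f}")

print(
    "\nAcetate enrichment shifts the product slate from LA toward PHB without\n"
    "touching the solid line (char/tar identical within a feedstock), but the\n"
    "acetate + nutrient bill outweighs the extra PHB revenue, so the plain-liquor\n"
    "alternatives carry the better NPV and IRR."
)
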