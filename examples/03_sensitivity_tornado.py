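"""One-at-a-time sensitivity: cost-variable tornado and the operational case study.

The tornado perturbs each price by +/-20 % and ranks variables by the NPV
swing; the case-study table varies operational levers (feed availability,
LSR, washing water, steam price) one at a time and lists the resulting NPVs.
"""

import bioref as br

cfg = br.builtin_scenario("euc_without_acetate")

print("tornado (deterministic +/-20%):")
for r in br.tornado(cfg):
    print(f"  {r.rank}. {r.variable:<42} range {r.delta_range/1e6:>7.2f} MMUSD")

print("\noperational case study (NPV, USD, sorted best to worst):")
table = br.case_study_table(cfg)
for _, row in table.iterrows():
    print(f"  {row['change']:<13} {row['variable']:<42} {row['npv_usd']:>14,.0f}")

print(
    "\nChar and tar prices dominate the economics; among operational levers,\n"
    "feed availability ranks first (more throughput at sub-linear capital cost),\n"
    "then LSR and washing water, whose NPV effect runs through evaporator steam\n"
    "duty and evaporator/pretreatment capital."
)
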