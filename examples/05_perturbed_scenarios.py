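"""Generate perturbed and fully random scenario configurations.

`perturb_config` draws every parameter from a normal distribution around a
base scenario (the structure assumed by the sensitivity assessment);
`random_scenario` builds arbitrary valid configurations for stress-testing
the balances.  Both are pure functions of their seed.
"""

import numpy as np

import bioref as br

base = br.builtin_scenario("euc_without_acetate")
base_npv = br.evaluate(base)[1].npv_usd

npvs = []
for seed in range(50):
    cfg = br.perturb_config(base, br.PerturbationSpec(seed=seed))
    assert br.validate(cfg) == []
    npvs.append(br.evaluate(cfg)[1].npv_usd)
npvs = np.array(npvs) / 1e6

print(f"base NPV: {base_npv/1e6:.2f} MMUSD")
print(f"50 perturbed scenarios (sigma 10% process/prices, 5% yields):")
print(f"  NPV mean {npvs.mean():.2f} MMUSD, sd {npvs.std(ddof=1):.2f}, "
      f"range [{npvs.min():.2f}, {npvs.max():.2f}]")
print(f"  P(NPV > 0) = {np.mean(npvs > 0):.0%}")

worst = 0.0
for seed in range(20):
    result = br.run_scenario(br.random_scenario(seed))
    worst = max(worst, max(s.mass_closure() for s in result.stages.values()))
print(f"\nworst stage mass-balance closure over 20 random scenarios: {worst:.2e}")
print(
    "\nThe NPV distribution under joint +/-20%-scale uncertainty is wide\n"
    "compared with the base margin — consistent with the tornado result that\n"
    "a handful of prices dominate the outcome.  Mass conservation holds to\n"
    "numerical precision on arbitrary valid configurations."
)
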