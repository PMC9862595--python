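"""Synthetic scenario generation for property-based testing.

Two generators: :func:`perturb_config` draws each numeric parameter from a
normal distribution around a base configuration (the statistical structure
the sensitivity assessment assumes), clipped to its validity range and with
dependent constraints renormalized; :func:`random_scenario` builds a fully
random but valid scenario from documented plausible ranges that bracket the
two packaged feedstocks.  Both are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    Alternative,
    CapitalReference,
    ConversionParams,
    EconomicParams,
    FeedstockComposition,
    PretreatmentParams,
    PyrolysisParams,
    RecoveryParams,
    ScenarioConfig,
    get_by_path,
    set_by_path,
    validate,
)

__all__ = ["PerturbationSpec", "perturb_config", "random_scenario", "PERTURBABLE_PATHS"]


#: perturbable numeric leaves, grouped, with clip ranges keeping configs valid
PERTURBABLE_PATHS: dict[str, list[tuple[str, float, float]]] = {
    "process": [
        ("pretreatment.lsr", 1.5, 20.0),
        ("pretreatment.wash_water_per_ton_pulp", 0.0, 10.0),
        ("pretreatment.temperature_C", 150.0, 220.0),
        ("steam_economy", 1.0, 6.0),
        ("target_sugar_conc_gL", 100.0, 400.0),
        ("economics.annual_feed_t", 1_000.0, 500_000.0),
    ],
    "prices": [
        ("economics.prices.char_usd_per_t", 0.0, np.inf),
        ("economics.prices.tar_usd_per_t", 0.0, np.inf),
        ("economics.prices.la_usd_per_kg", 0.0, np.inf),
        ("economics.prices.phb_usd_per_kg", 0.0, np.inf),
        ("economics.prices.steam_usd_per_t", 0.0, np.inf),
        ("economics.prices.electricity_usd_per_mwh", 0.0, np.inf),
        ("economics.prices.feedstock_usd_per_t", 0.0, np.inf),
    ],
    "yields": [
        ("pretreatment.solid_yield", 0.3, 0.95),
        ("pretreatment.sugar_recovery_kg_per_ton", 0.0, 400.0),
        ("conversion.y_la", 0.0, 0.6),
        ("conversion.y_phb", 0.0, 0.4),
        ("pyrolysis.char_yield", 0.05, 0.6),
        ("pyrolysis.tar_yield", 0.05, 0.6),
        ("pyrolysis.gas_yield", 0.05, 0.6),
        ("pyrolysis.loss_yield", 0.01, 0.5),
    ],
}


@dataclass
class PerturbationSpec:
    """Relative sigma per parameter group; draws are clipped to validity ranges."""

    sigma_process: float = 0.10
    sigma_prices: float = 0.10
    sigma_yields: float = 0.05
    truncate: bool = True
    seed: int = 0

    def sigma_for(self, group: str) -> float:
        return {
            "process": self.sigma_process,
            "prices": self.sigma_prices,
            "yields": self.sigma_yields,
        }[group]

    def __post_init__(self) -> None:
        for s in (self.sigma_process, self.sigma_prices, self.sigma_yields):
            if s < 0:
                raise ValueError("sigma fractions must be >= 0")


def _renormalize(config: ScenarioConfig) -> ScenarioConfig:
    """Restore dependent constraints after independent draws."""
    py = config.pyrolysis
    total = py.yield_sum()
    for name in ("char_yield", "tar_yield", "gas_yield", "loss_yield"):
        object.__setattr__(py, name, getattr(py, name) / total)
    # residual solid + recovered sugar cannot exceed the dry ton
    p = config.pretreatment
    max_sugar = (1.0 - p.solid_yield) * 1000.0
    if p.sugar_recovery_kg_per_ton > max_sugar:
        object.__setattr__(p, "sugar_recovery_kg_per_ton", max_sugar)
    c = config.conversion
    if c.y_la + c.y_phb > 1.0:
        s = c.y_la + c.y_phb
        object.__setattr__(c, "y_la", c.y_la / s)
        object.__setattr__(c, "y_phb", c.y_phb / s)
    return config


def perturb_config(base: ScenarioConfig, spec: PerturbationSpec) -> ScenarioConfig:
    """Draw every listed parameter from N(base, sigma*base), clipped, renormalized.

    With all sigmas zero the output equals the base exactly.  The result
    always passes :func:`bioref.config.validate`.
    """
    if validate(base):
        raise ValueError("base config must be valid")
    rng = np.random.default_rng(spec.seed)
    out = base.model_copy(deep=True)
    for group, paths in PERTURBABLE_PATHS.items():
        sigma = spec.sigma_for(group)
        for path, lo, hi in paths:
            value = get_by_path(out, path)
            draw = rng.normal(value, sigma * abs(value)) if sigma > 0 else value
            if spec.truncate:
                draw = float(np.clip(draw, lo, hi))
            out = set_by_path(out, path, float(draw))
    out = _renormalize(out)
    violations = validate(out)
    if violations:
        raise ValueError(f"perturbation left config invalid: {violations}")
    return out


def random_scenario(seed: int) -> ScenarioConfig:
    """A fully random, valid scenario; documented ranges bracket both feedstocks.

    Ranges: solid yield 0.5-0.9, LSR 4-12, wash water 2-5 t/t, conversion
    yields up to ~0.5 combined, pyrolysis fractions on the simplex, feed
    10-100 kt/yr.
    """
    rng = np.random.default_rng(seed)
    # composition on the simplex, scaled so fractions sum to <= 1
    raw = rng.dirichlet(np.ones(8))  # last entry = unclassified remainder
    comp = FeedstockComposition(
        glucans=raw[0], xylans=raw[1], arabinans=raw[2], acetyl_groups=raw[3],
        lignin=raw[4], extractives=raw[5], ash=raw[6],
    )
    solid_yield = rng.uniform(0.5, 0.9)
    sugar_recovery = rng.uniform(0.1, 0.9) * (1.0 - solid_yield) * 1000.0
    pyro = rng.dirichlet(np.ones(4) * 5.0)
    y_la = rng.uniform(0.05, 0.4)
    y_phb = rng.uniform(0.0, 0.5 - y_la)
    with_acetate = bool(rng.integers(0, 2))
    lsr = rng.uniform(4.0, 12.0)

    feed = rng.uniform(10_000.0, 100_000.0)
    blocks = [
        CapitalReference(name="pretreatment", co_usd=rng.uniform(5e6, 50e6),
                         mo=feed * (1 + lsr), capacity_key="slurry_t", n_exponent=0.7),
        CapitalReference(name="conversion", co_usd=rng.uniform(5e6, 80e6),
                         mo=max(feed * sugar_recovery / 1000.0, 1.0),
                         capacity_key="sugars_t", n_exponent=rng.uniform(0.6, 0.8)),
        CapitalReference(name="pyrolysis", co_usd=rng.uniform(2e6, 30e6),
                         mo=feed * solid_yield, capacity_key="pyrolysis_feed_t",
                         n_exponent=rng.uniform(0.6, 0.8)),
    ]
    prices = {
        "feedstock_usd_per_t": rng.uniform(3.0, 20.0),
        "water_usd_per_m3": rng.uniform(0.2, 2.0),
        "electricity_usd_per_mwh": rng.uniform(40.0, 150.0),
        "steam_usd_per_t": rng.uniform(5.0, 25.0),
        "h2so4_usd_per_kg": rng.uniform(0.05, 0.3),
        "nutrients_usd_per_kg": rng.uniform(2.0, 20.0),
        "acetate_usd_per_t": rng.uniform(200.0, 800.0),
        "waste_treatment_usd_per_m3": rng.uniform(0.5, 3.0),
        "char_usd_per_t": rng.uniform(100.0, 2000.0),
        "tar_usd_per_t": rng.uniform(100.0, 2000.0),
        "phb_usd_per_kg": rng.uniform(2.0, 10.0),
        "la_usd_per_kg": rng.uniform(1.0, 6.0),
    }
    config = ScenarioConfig(
        name=f"synthetic_{seed}",
        feedstock=comp,
        pretreatment=PretreatmentParams(
            temperature_C=rng.uniform(160.0, 200.0),
            lsr=lsr,
            time_min=rng.uniform(10.0, 60.0),
            wash_water_per_ton_pulp=rng.uniform(2.0, 5.0),
            solid_yield=solid_yield,
            sugar_recovery_kg_per_ton=sugar_recovery,
        ),
        liquor_composition={
            "glucose": rng.uniform(5.0, 20.0),
            "xylose": rng.uniform(100.0, 160.0),
            "arabinose": rng.uniform(0.0, 10.0),
            "acetic_acid": rng.uniform(5.0, 25.0),
            "furfural": rng.uniform(0.0, 12.0),
        },
        target_sugar_conc_gL=rng.uniform(150.0, 250.0),
        steam_economy=rng.uniform(2.0, 4.0),
        conversion=ConversionParams(
            alternative=Alternative.WITH_ACETATE if with_acetate else Alternative.WITHOUT_ACETATE,
            y_la=y_la,
            y_phb=y_phb,
            acetate_fraction_of_carbon=0.5 if with_acetate else 0.0,
        ),
        recovery=RecoveryParams(),
        pyrolysis=PyrolysisParams(
            char_yield=float(pyro[0]), tar_yield=float(pyro[1]),
            gas_yield=float(pyro[2]), loss_yield=float(pyro[3]),
            feed_moisture=0.5,
        ),
        economics=EconomicParams(
            annual_feed_t=feed,
            prices=prices,
            labor_hours_per_year=rng.uniform(100_000.0, 800_000.0),
            discount_rate=rng.uniform(0.08, 0.2),
            capital_blocks=blocks,
        ),
    )
    violations = validate(config)
    assert not violations, violations
    return config
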