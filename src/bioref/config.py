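"""Scenario configuration: domain types, validation, file IO, packaged scenarios.

A :class:`ScenarioConfig` bundles everything needed to simulate one
biorefinery scenario: feedstock composition, autohydrolysis pretreatment,
liquor concentration and post-hydrolysis, mixed-microbial-culture conversion
to levulinic acid (LA) and polyhydroxybutyrate (PHB), product recovery, slow
pyrolysis of the residual solid, and the economic parameter set (unit prices,
financial assumptions, capital-cost reference blocks).

Configs are plain pydantic models; field-level typing is intentionally loose
(floats, not constrained types) so that deliberately invalid configs can be
constructed and reported on by :func:`validate`, which is the single source of
truth for the physical invariants.  :func:`load_scenario` runs it and raises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict

__all__ = [
    "Alternative",
    "FeedstockComposition",
    "PretreatmentParams",
    "ConversionParams",
    "RecoveryParams",
    "PyrolysisParams",
    "EconomicParams",
    "CapitalReference",
    "ScenarioConfig",
    "Violation",
    "ConfigValidationError",
    "validate",
    "load_scenario",
    "save_scenario",
    "builtin_scenarios",
    "builtin_scenario",
    "BUILTIN_NAMES",
    "get_by_path",
    "set_by_path",
    "scale_by_path",
]


class Alternative(str, Enum):
    """Microbial-culture alternative: plain liquor (I) or acetate-enriched (II)."""

    WITHOUT_ACETATE = "without_acetate"
    WITH_ACETATE = "with_acetate"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class FeedstockComposition(_Model):
    """Dry-basis mass fractions of the raw material (remainder is unclassified)."""

    glucans: float
    xylans: float
    arabinans: float = 0.0
    acetyl_groups: float = 0.0
    lignin: float = 0.0
    extractives: float = 0.0
    ash: float = 0.0

    def total(self) -> float:
        return (
            self.glucans
            + self.xylans
            + self.arabinans
            + self.acetyl_groups
            + self.lignin
            + self.extractives
            + self.ash
        )


class PretreatmentParams(_Model):
    """Autohydrolysis + washing parameters.

    ``solid_yield`` and ``sugar_recovery_kg_per_ton`` are calibration
    constants: the dry residual-solid fraction and the monomeric
    hemicellulosic sugar recovered in the post-hydrolyzed liquor per oven-dry
    ton of feed.
    """

    temperature_C: float
    lsr: float  # liquid-to-solid ratio, t water / t dry feed
    time_min: float
    wash_water_per_ton_pulp: float  # t water / t dry pulp
    solid_yield: float  # dry residual solid, fraction of dry feed
    sugar_recovery_kg_per_ton: float  # kg sugar / dry t feed


class ConversionParams(_Model):
    """Mixed-microbial-culture conversion of liquor sugars to LA and PHB."""

    alternative: Alternative
    y_la: float  # LA mass yield on total carbon source
    y_phb: float  # PHB mass yield on total carbon source
    acetate_fraction_of_carbon: float  # fraction of carbon source that is acetate
    culture_temp_C: float = 25.0
    culture_days: float = 40.0
    culture_energy_MJ_per_kg_product: float = 5.0


class RecoveryParams(_Model):
    phb_recovery_cost_usd_per_kg: float = 1.0
    phb_recovery_energy_MJ_per_kg: float = 2.0
    la_recovery_energy_kWh_per_kg: float = 8.0


class PyrolysisParams(_Model):
    """Slow pyrolysis of the (dried) residual solid, plus the boiler alternative."""

    char_yield: float = 0.35
    tar_yield: float = 0.25
    gas_yield: float = 0.25
    loss_yield: float = 0.15
    pyrolysis_energy_MJ_per_kg: float = 1.35  # MJ / kg dry solid fed
    gas_self_supply: bool = True
    gas_lhv_MJ_per_kg: float = 15.0  # energy credit of pyrolysis gases
    feed_moisture: float = 0.50  # wet-basis water fraction entering drying
    lhv_MJ_per_kg: float = 15.0  # dry solid LHV, boiler alternative
    boiler_efficiency: float = 0.80

    def yield_sum(self) -> float:
        return self.char_yield + self.tar_yield + self.gas_yield + self.loss_yield


class CapitalReference(_Model):
    """One equipment block for power-law capital scaling C = Co (M/Mo)^n."""

    name: str
    co_usd: float
    mo: float
    capacity_key: str  # which ScenarioResult capacity drives M
    n_exponent: float = 0.7
    installation_factor: float = 1.0


class PostHydrolysisParams(_Model):
    acid_wt_fraction: float = 0.01
    temperature_C: float = 121.0
    time_min: float = 60.0


class EconomicParams(_Model):
    annual_feed_t: float  # dry t/yr
    prices: dict[str, float]  # unit embedded in key, e.g. "char_usd_per_t"
    labor_rate_usd_per_h: float = 15.0
    labor_hours_per_year: float = 650_000.0
    maintenance_taxes_fraction_of_tci: float = 0.02
    income_tax_rate: float = 0.35
    discount_rate: float = 0.15
    project_lifetime_years: int = 20
    depreciation_years: int = 10
    nutrient_dose_kg_per_t_carbon: float = 20.0
    capital_blocks: list[CapitalReference] = []


#: price keys every scenario must carry (unit is part of the key)
REQUIRED_PRICE_KEYS = (
    "feedstock_usd_per_t",
    "water_usd_per_m3",
    "electricity_usd_per_mwh",
    "steam_usd_per_t",
    "h2so4_usd_per_kg",
    "nutrients_usd_per_kg",
    "acetate_usd_per_t",
    "waste_treatment_usd_per_m3",
    "char_usd_per_t",
    "tar_usd_per_t",
    "phb_usd_per_kg",
    "la_usd_per_kg",
)


class ScenarioConfig(_Model):
    name: str
    feedstock: FeedstockComposition
    pretreatment: PretreatmentParams
    liquor_composition: dict[str, float]  # component -> g/L after post-hydrolysis
    target_sugar_conc_gL: float = 200.0
    steam_economy: float = 2.6  # kg water evaporated / kg steam
    posthydrolysis: PostHydrolysisParams = PostHydrolysisParams()
    conversion: ConversionParams
    recovery: RecoveryParams = RecoveryParams()
    pyrolysis: PyrolysisParams = PyrolysisParams()
    economics: EconomicParams

    # physical constants, exposed for override but rarely touched
    slurry_heat_capacity_kJ_per_kgK: float = 4.0
    steam_enthalpy_MJ_per_t: float = 2244.0
    latent_heat_kJ_per_kg: float = 2260.0
    ambient_temp_C: float = 25.0


@dataclass(frozen=True)
class Violation:
    """One invariant failure: which field, which rule, what was observed."""

    field: str
    rule: str
    value: Any

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule} (observed {self.value!r})"


class ConfigValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "invalid scenario configuration:\n"
            + "\n".join(f"  - {v}" for v in violations)
        )


def validate(config: ScenarioConfig) -> list[Violation]:
    """Check every cross-field invariant; returns an empty list iff valid."""
    v: list[Violation] = []
    f = config.feedstock
    for name in ("glucans", "xylans", "arabinans", "acetyl_groups", "lignin", "extractives", "ash"):
        x = getattr(f, name)
        if not 0.0 <= x <= 1.0:
            v.append(Violation(f"feedstock.{name}", "fraction must be in [0, 1]", x))
    if f.total() > 1.0 + 1e-9:
        v.append(Violation("feedstock", "fractions must sum to <= 1", f.total()))

    p = config.pretreatment
    if p.lsr <= 0:
        v.append(Violation("pretreatment.lsr", "must be > 0", p.lsr))
    if not 0.0 < p.solid_yield < 1.0:
        v.append(Violation("pretreatment.solid_yield", "must be in (0, 1)", p.solid_yield))
    if p.sugar_recovery_kg_per_ton < 0:
        v.append(Violation("pretreatment.sugar_recovery_kg_per_ton", "must be >= 0", p.sugar_recovery_kg_per_ton))
    if p.solid_yield * 1000.0 + p.sugar_recovery_kg_per_ton > 1000.0 + 1e-9:
        v.append(
            Violation(
                "pretreatment",
                "solid_yield and recovered sugar jointly exceed 1 t per dry t feed",
                (p.solid_yield, p.sugar_recovery_kg_per_ton),
            )
        )
    if p.wash_water_per_ton_pulp < 0:
        v.append(Violation("pretreatment.wash_water_per_ton_pulp", "must be >= 0", p.wash_water_per_ton_pulp))

    c = config.conversion
    if c.y_la < 0 or c.y_phb < 0:
        v.append(Violation("conversion", "yields must be >= 0", (c.y_la, c.y_phb)))
    if c.y_la + c.y_phb > 1.0 + 1e-9:
        v.append(Violation("conversion", "y_la+y_phb>1", (c.y_la, c.y_phb)))
    if not 0.0 <= c.acetate_fraction_of_carbon < 1.0:
        v.append(Violation("conversion.acetate_fraction_of_carbon", "must be in [0, 1)", c.acetate_fraction_of_carbon))
    if c.culture_energy_MJ_per_kg_product < 0:
        v.append(Violation("conversion.culture_energy_MJ_per_kg_product", "must be >= 0", c.culture_energy_MJ_per_kg_product))

    r = config.recovery
    for name in ("phb_recovery_cost_usd_per_kg", "phb_recovery_energy_MJ_per_kg", "la_recovery_energy_kWh_per_kg"):
        x = getattr(r, name)
        if x < 0:
            v.append(Violation(f"recovery.{name}", "must be >= 0", x))

    py = config.pyrolysis
    if abs(py.yield_sum() - 1.0) > 1e-9:
        v.append(Violation("pyrolysis", "char+tar+gas+loss yields must sum to 1", py.yield_sum()))
    for name in ("char_yield", "tar_yield", "gas_yield", "loss_yield"):
        x = getattr(py, name)
        if x < 0:
            v.append(Violation(f"pyrolysis.{name}", "must be >= 0", x))
    if not 0.0 <= py.boiler_efficiency <= 1.0:
        v.append(Violation("pyrolysis.boiler_efficiency", "must be in [0, 1]", py.boiler_efficiency))
    if not 0.0 <= py.feed_moisture < 1.0:
        v.append(Violation("pyrolysis.feed_moisture", "must be in [0, 1)", py.feed_moisture))
    if py.lhv_MJ_per_kg < 0:
        v.append(Violation("pyrolysis.lhv_MJ_per_kg", "must be >= 0", py.lhv_MJ_per_kg))

    e = config.economics
    if e.annual_feed_t < 0:
        v.append(Violation("economics.annual_feed_t", "must be >= 0", e.annual_feed_t))
    if e.discount_rate <= 0:
        v.append(Violation("economics.discount_rate", "must be > 0", e.discount_rate))
    if e.project_lifetime_years < 1:
        v.append(Violation("economics.project_lifetime_years", "must be >= 1", e.project_lifetime_years))
    for key in REQUIRED_PRICE_KEYS:
        if key not in e.prices:
            v.append(Violation(f"economics.prices.{key}", "required price missing", None))
        elif e.prices[key] < 0:
            v.append(Violation(f"economics.prices.{key}", "must be >= 0", e.prices[key]))
    for blk in e.capital_blocks:
        if blk.co_usd < 0 or blk.mo <= 0:
            v.append(Violation(f"economics.capital_blocks[{blk.name}]", "co_usd >= 0 and mo > 0 required", (blk.co_usd, blk.mo)))
        if not 0.0 < blk.n_exponent <= 1.0:
            v.append(Violation(f"economics.capital_blocks[{blk.name}].n_exponent", "must be in (0, 1]", blk.n_exponent))

    if config.target_sugar_conc_gL <= 0:
        v.append(Violation("target_sugar_conc_gL", "must be > 0", config.target_sugar_conc_gL))
    if config.steam_economy <= 0:
        v.append(Violation("steam_economy", "must be > 0", config.steam_economy))
    return v


# ---------------------------------------------------------------------------
# file IO


def _to_tree(config: ScenarioConfig) -> dict:
    return json.loads(config.model_dump_json())


def _from_tree(tree: dict, source: str) -> ScenarioConfig:
    try:
        return ScenarioConfig.model_validate(tree)
    except pydantic.ValidationError as exc:
        violations = [
            Violation(".".join(str(p) for p in err["loc"]), err["msg"], err.get("input"))
            for err in exc.errors()
        ]
        raise ConfigValidationError(violations) from exc


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario from a YAML or JSON file.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`ConfigValidationError` (naming the offending fields) for a file
    that parses but violates the schema or a physical invariant.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        tree = json.loads(text)
    else:
        tree = yaml.safe_load(text)
    config = _from_tree(tree, str(path))
    violations = validate(config)
    if violations:
        raise ConfigValidationError(violations)
    return config


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario to YAML (default) or JSON, round-trip safe."""
    path = Path(path)
    tree = _to_tree(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(tree, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(tree, sort_keys=False))


# ---------------------------------------------------------------------------
# packaged scenarios

BUILTIN_NAMES = (
    "euc_without_acetate",
    "euc_with_acetate",
    "scb_without_acetate",
    "scb_with_acetate",
)


def builtin_scenario(name: str) -> ScenarioConfig:
    """Load one packaged scenario by name (see :data:`BUILTIN_NAMES`)."""
    if name not in BUILTIN_NAMES:
        raise KeyError(f"unknown builtin scenario {name!r}; available: {BUILTIN_NAMES}")
    ref = resources.files("bioref.data").joinpath(f"{name}.yaml")
    tree = yaml.safe_load(ref.read_text())
    config = _from_tree(tree, name)
    violations = validate(config)
    if violations:  # pragma: no cover - packaged files are valid
        raise ConfigValidationError(violations)
    return config


def builtin_scenarios() -> list[ScenarioConfig]:
    """The four packaged scenarios: EUC/SCB x without/with acetate."""
    return [builtin_scenario(name) for name in BUILTIN_NAMES]


# ---------------------------------------------------------------------------
# dotted-path access (used by sensitivity and synthetic perturbation)


def _resolve(obj: Any, parts: list[str]) -> tuple[Any, str]:
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj, parts[-1]


def get_by_path(config: ScenarioConfig, path: str) -> Any:
    """Read a (possibly nested) field via a dotted path like ``pretreatment.lsr``."""
    try:
        parent, leaf = _resolve(config, path.split("."))
        return parent[leaf] if isinstance(parent, dict) else getattr(parent, leaf)
    except (AttributeError, KeyError) as exc:
        raise KeyError(f"unknown config path {path!r}") from exc


def set_by_path(config: ScenarioConfig, path: str, value: Any) -> ScenarioConfig:
    """Return a deep copy of ``config`` with the field at ``path`` replaced."""
    out = config.model_copy(deep=True)
    try:
        parent, leaf = _resolve(out, path.split("."))
        if isinstance(parent, dict):
            if leaf not in parent:
                raise KeyError(leaf)
            parent[leaf] = value
        else:
            getattr(parent, leaf)  # raise if absent
            object.__setattr__(parent, leaf, value)
    except (AttributeError, KeyError) as exc:
        raise KeyError(f"unknown config path {path!r}") from exc
    return out


def scale_by_path(config: ScenarioConfig, path: str, factor: float) -> ScenarioConfig:
    """Return a deep copy with the numeric field at ``path`` multiplied by ``factor``."""
    value = get_by_path(config, path)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise TypeError(f"config path {path!r} is not numeric (got {type(value).__name__})")
    return set_by_path(config, path, value * factor)
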