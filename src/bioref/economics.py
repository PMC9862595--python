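"""Capital and operating costs, cash flows, NPV/IRR, minimum selling price.

Capital follows the classic power-law scaling C = Co * (M/Mo)^n per equipment
block, with the block capacity M taken from the scenario result (slurry feed,
water evaporated, sugar throughput, pyrolysis feed).  Operating cost and
revenue are built from the scenario's annual flows and the configured unit
prices.  The cash-flow table uses straight-line depreciation, a single
year-0 investment, and tax on positive taxable income only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import CapitalReference, ScenarioConfig, set_by_path
from .process import ScenarioResult, run_scenario

__all__ = [
    "CashFlowTable",
    "EconomicResult",
    "scaled_capital_cost",
    "total_capital_investment",
    "annual_opex",
    "annual_revenue",
    "build_cash_flow",
    "npv",
    "irr",
    "evaluate",
    "minimum_selling_price",
]


@dataclass
class CashFlowTable:
    """Year-indexed flows (year 0 = investment) underlying NPV and IRR."""

    years: np.ndarray
    capital_outlay: np.ndarray
    revenue: np.ndarray
    opex: np.ndarray
    depreciation: np.ndarray
    tax: np.ndarray
    net_cash: np.ndarray
    discount_rate: float

    @property
    def discounted_net(self) -> np.ndarray:
        return self.net_cash / (1.0 + self.discount_rate) ** self.years

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "capital": self.capital_outlay,
                "revenue": self.revenue,
                "opex": self.opex,
                "depreciation": self.depreciation,
                "tax": self.tax,
                "net": self.net_cash,
                "discounted": self.discounted_net,
            }
        )


@dataclass
class EconomicResult:
    """Headline economics of one scenario."""

    tci_usd: float
    npv_usd: float
    irr: float | None
    opex_breakdown: dict[str, float] = field(default_factory=dict)
    revenue_breakdown: dict[str, float] = field(default_factory=dict)
    cash_flow: CashFlowTable | None = None

    @property
    def annual_opex_usd(self) -> float:
        return sum(self.opex_breakdown.values())

    @property
    def annual_revenue_usd(self) -> float:
        return sum(self.revenue_breakdown.values())


def scaled_capital_cost(ref: CapitalReference, capacity: float) -> float:
    """Installed cost of one block at ``capacity``: Co*(M/Mo)^n * install factor."""
    if capacity <= 0:
        raise ValueError(f"capacity for block {ref.name!r} must be > 0, got {capacity}")
    return ref.co_usd * (capacity / ref.mo) ** ref.n_exponent * ref.installation_factor


def total_capital_investment(config: ScenarioConfig, result: ScenarioResult) -> float:
    """Sum the scaled costs of every capital block at the scenario's capacities."""
    total = 0.0
    for blk in config.economics.capital_blocks:
        if blk.capacity_key not in result.capacities:
            raise KeyError(
                f"capital block {blk.name!r} needs capacity {blk.capacity_key!r}; "
                f"available: {sorted(result.capacities)}"
            )
        if blk.co_usd == 0.0:
            continue
        total += scaled_capital_cost(blk, result.capacities[blk.capacity_key])
    return total


def annual_opex(
    config: ScenarioConfig, result: ScenarioResult, tci_usd: float | None = None
) -> dict[str, float]:
    """Operating cost breakdown (USD/yr) priced from the config's unit prices."""
    e = config.economics
    p = e.prices

    def price(key: str) -> float:
        if key not in p:
            raise KeyError(f"missing price {key!r} in economics.prices")
        return p[key]

    if tci_usd is None:
        tci_usd = total_capital_investment(config, result)
    cons = result.consumables
    items = {
        "raw_material": e.annual_feed_t * price("feedstock_usd_per_t"),
        "water": result.utility_water_m3 * price("water_usd_per_m3"),
        "steam": result.total_steam_t * price("steam_usd_per_t"),
        "electricity": result.total_electricity_kWh / 1000.0 * price("electricity_usd_per_mwh"),
        "h2so4": cons.get("h2so4_t", 0.0) * 1000.0 * price("h2so4_usd_per_kg"),
        "nutrients": cons.get("nutrients_kg", 0.0) * price("nutrients_usd_per_kg"),
        "acetate": cons.get("acetate_t", 0.0) * price("acetate_usd_per_t"),
        "phb_recovery": cons.get("phb_recovery_kg", 0.0) * config.recovery.phb_recovery_cost_usd_per_kg,
        "labor": e.labor_rate_usd_per_h * e.labor_hours_per_year,
        "maintenance_taxes": e.maintenance_taxes_fraction_of_tci * tci_usd,
        "waste_treatment": result.waste_water_m3 * price("waste_treatment_usd_per_m3"),
    }
    return items


def annual_revenue(config: ScenarioConfig, result: ScenarioResult) -> dict[str, float]:
    """Revenue breakdown (USD/yr): product mass times unit price."""
    p = config.economics.prices
    for key in ("char_usd_per_t", "tar_usd_per_t", "phb_usd_per_kg", "la_usd_per_kg"):
        if p.get(key, 0.0) < 0:
            raise ValueError(f"negative price {key}")
    prod = result.products
    return {
        "char": prod["char"] * p["char_usd_per_t"],
        "tar": prod["tar"] * p["tar_usd_per_t"],
        "phb": prod["phb"] * 1000.0 * p["phb_usd_per_kg"],
        "la": prod["la"] * 1000.0 * p["la_usd_per_kg"],
    }


def build_cash_flow(
    config: ScenarioConfig,
    tci_usd: float,
    revenue_usd: float,
    opex_usd: float,
) -> CashFlowTable:
    """Constant-operation cash-flow table over the project lifetime.

    Investment at year 0, straight-line depreciation over
    ``depreciation_years``, income tax on max(0, revenue - opex -
    depreciation); no loss carry-forward, salvage or working capital.
    """
    e = config.economics
    n = e.project_lifetime_years
    years = np.arange(n + 1)
    capital = np.zeros(n + 1)
    capital[0] = tci_usd
    revenue = np.where(years >= 1, revenue_usd, 0.0)
    opex = np.where(years >= 1, opex_usd, 0.0)
    dep = np.where(
        (years >= 1) & (years <= e.depreciation_years), tci_usd / e.depreciation_years, 0.0
    )
    taxable = revenue - opex - dep
    tax = e.income_tax_rate * np.clip(taxable, 0.0, None)
    net = revenue - opex - tax - capital
    return CashFlowTable(
        years=years,
        capital_outlay=capital,
        revenue=revenue,
        opex=opex,
        depreciation=dep,
        tax=tax,
        net_cash=net,
        discount_rate=e.discount_rate,
    )


def npv(cashflows: CashFlowTable, discount_rate: float | None = None) -> float:
    """Net present value of the table at the given (or its own) discount rate."""
    r = cashflows.discount_rate if discount_rate is None else discount_rate
    if r <= -1.0:
        raise ValueError("discount rate must be > -1")
    return float(np.sum(cashflows.net_cash / (1.0 + r) ** cashflows.years))


def irr(
    cashflows: CashFlowTable, lo: float = -0.99, hi: float = 10.0, tol_usd: float = 1.0
) -> float | None:
    """Internal rate of return by bracketing + Brent root finding.

    Returns ``None`` when the NPV(r) curve has no sign change on
    ``(lo, hi)`` (e.g. all-negative flows), matching conventional-flow
    semantics.
    """
    signs = np.sign(cashflows.net_cash[cashflows.net_cash != 0])
    if signs.size == 0 or np.all(signs == signs[0]):
        return None
    grid = np.concatenate([np.linspace(lo, 1.0, 200), np.linspace(1.0, hi, 90)[1:]])
    vals = np.array([npv(cashflows, r) for r in grid])
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if idx.size == 0:
        return None
    a, b = grid[idx[0]], grid[idx[0] + 1]
    root = brentq(lambda r: npv(cashflows, r), a, b, xtol=1e-10)
    if abs(npv(cashflows, root)) > tol_usd:
        return None  # pragma: no cover - brentq converges well below tolerance
    return float(root)


def evaluate(
    config: ScenarioConfig, result: ScenarioResult | None = None
) -> tuple[ScenarioResult, EconomicResult]:
    """Run the flowsheet (unless given) and the full economic build-up."""
    if result is None:
        result = run_scenario(config)
    tci = total_capital_investment(config, result)
    opex = annual_opex(config, result, tci)
    revenue = annual_revenue(config, result)
    table = build_cash_flow(config, tci, sum(revenue.values()), sum(opex.values()))
    return result, EconomicResult(
        tci_usd=tci,
        npv_usd=npv(table),
        irr=irr(table),
        opex_breakdown=opex,
        revenue_breakdown=revenue,
        cash_flow=table,
    )


_PRODUCT_PRICE_PATHS = {
    "phb": "economics.prices.phb_usd_per_kg",
    "la": "economics.prices.la_usd_per_kg",
    "char": "economics.prices.char_usd_per_t",
    "tar": "economics.prices.tar_usd_per_t",
}


def minimum_selling_price(
    config: ScenarioConfig,
    product: str,
    *,
    upper_usd: float | None = None,
    tol_usd: float = 1_000.0,
) -> float:
    """Price of ``product`` (in its configured unit) at which NPV crosses zero.

    NPV is linear and increasing in each product price, so a bracketed root
    on [0, upper] is exact; raises if NPV stays negative even at the upper
    bound.  The default upper bound is 100 for per-kg products (PHB, LA) and
    100,000 for per-tonne products (char, tar).
    """
    if product not in _PRODUCT_PRICE_PATHS:
        raise KeyError(
            f"unknown product {product!r}; expected one of {sorted(_PRODUCT_PRICE_PATHS)}"
        )
    if upper_usd is None:
        upper_usd = 100.0 if product in ("phb", "la") else 100_000.0
    path = _PRODUCT_PRICE_PATHS[product]
    result = run_scenario(config)  # price changes do not alter the mass balance

    def npv_at(price: float) -> float:
        cfg = set_by_path(config, path, price)
        return evaluate(cfg, result)[1].npv_usd

    hi = npv_at(upper_usd)
    if hi < 0:
        raise ValueError(
            f"NPV still negative ({hi:.0f} USD) at {product} price {upper_usd}; "
            "raise upper_usd"
        )
    lo = npv_at(0.0)
    if lo >= 0:
        return 0.0
    price = brentq(npv_at, 0.0, upper_usd, xtol=1e-6)
    assert abs(npv_at(price)) <= tol_usd
    return float(price)
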