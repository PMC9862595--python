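"""One-at-a-time (OAT) sensitivity, tornado ranking, and the case-study table.

Each variable is a dotted path into the scenario config (e.g.
``economics.prices.char_usd_per_t`` or ``pretreatment.lsr``).  For every
perturbation the whole pipeline — mass/energy balance, capital scaling,
cash flow — is rerun, so process variables propagate through steam duty,
capital cost and waste volumes, not just through a single price line.

Two modes mirror the usual practice: deterministic +/-20 % endpoints, and
normal sampling around the base value (sigma = 10 % of base, so +/-20 %
corresponds to about two standard deviations) reporting 5th/95th percentile
NPVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig, get_by_path, scale_by_path
from .economics import evaluate

__all__ = [
    "SensitivitySpec",
    "SensitivityResult",
    "oat_delta",
    "tornado",
    "case_study_table",
    "DEFAULT_COST_VARIABLES",
    "CASE_STUDY_ROWS",
]

#: the cost-side tornado set: prices of products and main consumables
DEFAULT_COST_VARIABLES = (
    "economics.prices.char_usd_per_t",
    "economics.prices.tar_usd_per_t",
    "economics.prices.la_usd_per_kg",
    "economics.prices.phb_usd_per_kg",
    "economics.prices.feedstock_usd_per_t",
    "economics.prices.steam_usd_per_t",
    "economics.prices.electricity_usd_per_mwh",
    "economics.prices.nutrients_usd_per_kg",
    "economics.labor_rate_usd_per_h",
)

#: the operational case-study rows: (variable, direction of the favourable move)
CASE_STUDY_ROWS = (
    ("economics.annual_feed_t", +1),
    ("pretreatment.lsr", -1),
    ("pretreatment.wash_water_per_ton_pulp", -1),
    ("economics.prices.steam_usd_per_t", -1),
)


@dataclass
class SensitivitySpec:
    variation_fraction: float = 0.20
    mode: str = "deterministic_oat"  # or "normal_sampled"
    sigma_fraction: float = 0.10
    n_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.variation_fraction < 1.0:
            raise ValueError("variation_fraction must be in (0, 1)")
        if self.mode not in ("deterministic_oat", "normal_sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "normal_sampled" and self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SensitivityResult:
    variable: str
    npv_low: float
    npv_base: float
    npv_high: float
    rank: int = 0

    @property
    def delta_range(self) -> float:
        return abs(self.npv_high - self.npv_low)


def oat_delta(
    config: ScenarioConfig, variable: str, direction: int, fraction: float = 0.20
) -> float:
    """NPV after scaling one variable by (1 + direction*fraction); base untouched."""
    if direction not in (-1, 0, 1):
        raise ValueError("direction must be -1, 0 or +1")
    value = get_by_path(config, variable)  # raises KeyError for unknown paths
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise TypeError(f"variable {variable!r} is not numeric")
    perturbed = scale_by_path(config, variable, 1.0 + direction * fraction)
    return evaluate(perturbed)[1].npv_usd


def tornado(
    config: ScenarioConfig,
    variables: list[str] | tuple[str, ...] = DEFAULT_COST_VARIABLES,
    spec: SensitivitySpec | None = None,
) -> list[SensitivityResult]:
    """Per-variable NPV swing, sorted by range (widest bar first).

    Deterministic mode evaluates the two +/-fraction endpoints; sampled mode
    draws ``n_samples`` values per variable from N(base, sigma_fraction*base)
    with a seeded generator and reports the 5th/95th percentile NPVs.
    A variable that fails to evaluate raises with its name attached.
    """
    if not variables:
        raise ValueError("need at least one variable")
    spec = spec or SensitivitySpec()
    base_npv = evaluate(config)[1].npv_usd
    results: list[SensitivityResult] = []
    rng = np.random.default_rng(spec.seed)
    for var in variables:
        try:
            if spec.mode == "deterministic_oat":
                lo = oat_delta(config, var, -1, spec.variation_fraction)
                hi = oat_delta(config, var, +1, spec.variation_fraction)
            else:
                base_val = get_by_path(config, var)
                draws = rng.normal(base_val, spec.sigma_fraction * abs(base_val), spec.n_samples)
                draws = np.clip(draws, 0.0, None)  # prices/levels cannot go negative
                npvs = []
                for d in draws:
                    factor = d / base_val if base_val != 0 else 1.0
                    npvs.append(evaluate(scale_by_path(config, var, factor))[1].npv_usd)
                lo, hi = np.percentile(npvs, [5.0, 95.0])
        except Exception as exc:
            raise RuntimeError(f"sensitivity variable {var!r} failed: {exc}") from exc
        results.append(SensitivityResult(var, float(lo), base_npv, float(hi)))
    results.sort(key=lambda r: r.delta_range, reverse=True)
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


def case_study_table(
    config: ScenarioConfig,
    rows: tuple[tuple[str, int], ...] = CASE_STUDY_ROWS,
    fraction: float = 0.20,
) -> pd.DataFrame:
    """Accumulated-variation table: NPV of each one-sided 20 % move plus base.

    For every (variable, favourable direction) row both the favourable and
    the adverse move are evaluated; the output lists one line per move plus
    the base case, sorted by NPV descending.
    """
    records = [{"change": "base case", "variable": "-", "npv_usd": evaluate(config)[1].npv_usd}]
    for variable, direction in rows:
        for sign in (direction, -direction):
            label = "increase 20%" if sign > 0 else "reduce 20%"
            records.append(
                {
                    "change": label,
                    "variable": variable,
                    "npv_usd": oat_delta(config, variable, sign, fraction),
                }
            )
    frame = pd.DataFrame.from_records(records)
    return frame.sort_values("npv_usd", ascending=False, ignore_index=True)
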