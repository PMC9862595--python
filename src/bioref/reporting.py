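"""Report writers: stream/energy/cash-flow CSVs and the summary JSON.

All files use comma-separated UTF-8 with '.' decimals and a header row, and
contain no timestamps, so two runs of the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ScenarioConfig
from .economics import EconomicResult
from .process import ScenarioResult

__all__ = ["RunReport", "config_hash", "write_run_report"]


def config_hash(config: ScenarioConfig) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    canonical = json.dumps(
        json.loads(config.model_dump_json()), sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunReport:
    scenario: str
    config_sha256: str
    tool_version: str
    files: list[str]
    result: ScenarioResult
    economics: EconomicResult


def _streams_frame(result: ScenarioResult) -> pd.DataFrame:
    rows = []
    for stage_name, stage in result.stages.items():
        for stream in stage.outputs:
            for comp, mass in sorted(stream.components.items()):
                rows.append((stage_name, stream.label, comp, mass))
            if stream.water:
                rows.append((stage_name, stream.label, "water", stream.water))
    return pd.DataFrame(rows, columns=["stage", "stream", "component", "t_per_yr"])


def _energy_frame(result: ScenarioResult) -> pd.DataFrame:
    rows = [
        (name, stage.steam_demand_MJ, stage.electricity_demand_kWh)
        for name, stage in result.stages.items()
    ]
    return pd.DataFrame(rows, columns=["stage", "steam_MJ", "electricity_kWh"])


def write_run_report(
    config: ScenarioConfig,
    result: ScenarioResult,
    econ: EconomicResult,
    out_dir: str | Path,
) -> RunReport:
    """Write streams.csv, energy.csv, cash_flow.csv and summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    streams_path = out / "streams.csv"
    _streams_frame(result).to_csv(streams_path, index=False, float_format="%.6f")
    files.append(streams_path.name)

    energy_path = out / "energy.csv"
    _energy_frame(result).to_csv(energy_path, index=False, float_format="%.3f")
    files.append(energy_path.name)

    if econ.cash_flow is not None:
        cf_path = out / "cash_flow.csv"
        econ.cash_flow.to_frame().to_csv(cf_path, index=False, float_format="%.2f")
        files.append(cf_path.name)

    sha = config_hash(config)
    summary = {
        "scenario": config.name,
        "config_sha256": sha,
        "tool_version": __version__,
        "products_t_per_yr": {k: round(v, 3) for k, v in result.products.items()},
        "total_steam_t_per_yr": round(result.total_steam_t, 3),
        "total_electricity_kWh_per_yr": round(result.total_electricity_kWh, 1),
        "boiler_alternative_kWh_per_yr": round(result.boiler_alternative_kWh, 1),
        "utility_water_m3_per_yr": round(result.utility_water_m3, 1),
        "economics": {
            "tci_usd": round(econ.tci_usd, 2),
            "npv_usd": round(econ.npv_usd, 2),
            "irr": None if econ.irr is None else round(econ.irr, 6),
            "annual_revenue_usd": round(econ.annual_revenue_usd, 2),
            "annual_opex_usd": round(econ.annual_opex_usd, 2),
            "opex_breakdown_usd": {k: round(v, 2) for k, v in econ.opex_breakdown.items()},
            "revenue_breakdown_usd": {k: round(v, 2) for k, v in econ.revenue_breakdown.items()},
        },
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    files.append(summary_path.name)

    return RunReport(
        scenario=config.name,
        config_sha256=sha,
        tool_version=__version__,
        files=files,
        result=result,
        economics=econ,
    )
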