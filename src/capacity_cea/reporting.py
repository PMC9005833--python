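"""Tabular reporting of scenario economics.

Builds the headline results table — one row per constraint scenario with
the ICER, annual NMB, annual societal QALY gain, and the NMB/QALY
shortfall attributable to the constraint — in both machine (CSV, plain
numbers) and console (thousands separators) form.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .calibration import BaselineFixture
from .economics import (
    PopulationContext,
    ScenarioResult,
    evaluate_scenario,
    unconstrained_benchmark,
)
from .markov import DiscountSpec
from .pathway import scenario_presets

TABLE_COLUMNS = [
    "scenario",
    "icer",
    "annual_nmb",
    "annual_qaly_gain",
    "nmb_shortfall",
    "qaly_shortfall",
    "shortfall_pct",
]


def evaluate_presets(
    fixture: BaselineFixture,
    discount: DiscountSpec | None = None,
    threshold: float = 50_000.0,
    scenarios=None,
) -> list[ScenarioResult]:
    """Evaluate all preset scenarios (or a supplied subset) on a fixture."""
    discount = discount or DiscountSpec()
    pop = PopulationContext(n=fixture.n, threshold_lambda=threshold)
    if scenarios is None:
        scenarios = scenario_presets(
            fixture.test, fixture.crizotinib, fixture.docetaxel, discount, threshold
        )
    benchmark = unconstrained_benchmark(
        fixture.test, fixture.crizotinib, fixture.docetaxel, discount, threshold
    )
    return [
        evaluate_scenario(
            scn,
            fixture.test,
            fixture.crizotinib,
            fixture.docetaxel,
            pop,
            discount,
            benchmark=benchmark,
        )
        for scn in scenarios
    ]


def format_shortfall_pct(fraction: float) -> str:
    """Integer percent, except sub-1% shortfalls which keep one decimal."""
    pct = 100.0 * fraction
    if 0 < pct < 1:
        return f"{pct:.1f}"
    return f"{pct:.0f}"


def results_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Summary table: monetary cells to the nearest pound, QALYs to 2 dp."""
    rows = [
        {
            "scenario": r.name,
            "icer": round(r.icer),
            "annual_nmb": round(r.total_nmb),
            "annual_qaly_gain": round(r.qaly_gain, 2),
            "nmb_shortfall": round(r.vopi),
            "qaly_shortfall": round(r.qaly_shortfall, 2),
            "shortfall_pct": format_shortfall_pct(r.shortfall_fraction),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_results_table(results: list[ScenarioResult], path) -> pd.DataFrame:
    """Write the summary table as CSV (plain integers, no separators)."""
    table = results_table(results)
    table.to_csv(Path(path), index=False)
    return table


def console_table(results: list[ScenarioResult]) -> str:
    """Human-readable rendering with thousands separators."""
    table = results_table(results)
    pretty = table.copy()
    for col in ("icer", "annual_nmb", "nmb_shortfall"):
        pretty[col] = pretty[col].map(lambda v: f"£{v:,.0f}")
    pretty["shortfall_pct"] = pretty["shortfall_pct"].map(lambda v: f"{v}%")
    return pretty.to_string(index=False)
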