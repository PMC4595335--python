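"""Crop output-value accounting for the planting scenarios.

Net value per hectare is yield × price − input cost; district totals weight
these by the scenario's crop areas. Scenario areas are reported at one
decimal with sum-preserving (largest-remainder) rounding so the area
column of each scenario adds up exactly to the district's cultivated area,
matching how the district accounts are published.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .types import EconRecord, Scenario, ValidationError


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (monetary convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def unit_net_output(yield_kg_hm2: float, price_yuan_kg: float, unit_input_yuan_hm2: float) -> float:
    """Net output value per hectare: yield·price − input (yuan/hm²)."""
    if min(yield_kg_hm2, price_yuan_kg, unit_input_yuan_hm2) < 0:
        raise ValidationError("economics inputs must be nonnegative")
    return yield_kg_hm2 * price_yuan_kg - unit_input_yuan_hm2


def crop_area(total_cultivated: float, proportion: float) -> float:
    """Cultivated area of one crop (hm², 1 decimal)."""
    if not 0.0 <= proportion <= 1.0:
        raise ValidationError(f"proportion {proportion} outside [0, 1]")
    return round_half_up(total_cultivated * proportion, 1)


def scenario_areas(scenario: Scenario, total_cultivated: float) -> dict[str, float]:
    """Per-crop areas at 1 decimal that sum exactly to the total.

    Largest-remainder rounding: floor every area at 0.1 hm² resolution,
    then distribute the remaining tenths to the crops with the largest
    fractional parts (ties by declaration order).
    """
    raw = {c: total_cultivated * p for c, p in scenario.proportions.items()}
    floors = {c: math.floor(v * 10.0) for c, v in raw.items()}
    need = round(total_cultivated * 10.0) - sum(floors.values())
    if need < 0 or need > len(raw):
        raise ValidationError("area rounding cannot be reconciled with the total")
    order = sorted(raw, key=lambda c: raw[c] * 10.0 - floors[c], reverse=True)
    for c in order[:need]:
        floors[c] += 1
    return {c: floors[c] / 10.0 for c in raw}


def total_net_output(
    econ: dict[str, EconRecord], areas: dict[str, float]
) -> float:
    """District net output value (10⁶ yuan), unrounded."""
    missing = [c for c in areas if c not in econ]
    if missing:
        raise ValidationError(f"no economics record for crop(s) {missing}")
    return (
        math.fsum(
            unit_net_output(econ[c].yield_kg_hm2, econ[c].price_yuan_kg, econ[c].unit_input_yuan_hm2)
            * a
            for c, a in areas.items()
        )
        / 1e6
    )


def scenario_econ_compare(current_total: float, scenario_total: float) -> float:
    """Percent change of a scenario's total vs the current situation.

    Computed from unrounded totals and reported at 2 decimals.
    """
    if current_total <= 0:
        raise ValidationError("current total must be positive")
    return round_half_up(100.0 * (scenario_total - current_total) / current_total, 2)


@dataclass(frozen=True)
class EconResult:
    """District output-value accounts for a set of scenarios."""

    table: pd.DataFrame                 # per-crop rows, per-scenario area/value columns
    totals: dict[str, float]            # unrounded totals, 10⁶ yuan
    pct_change: dict[str, float]        # vs the baseline scenario

    def totals_rounded(self) -> dict[str, float]:
        return {k: round_half_up(v, 2) for k, v in self.totals.items()}


def evaluate_scenarios(
    econ: dict[str, EconRecord],
    scenarios: dict[str, Scenario],
    total_cultivated: float,
    baseline: str = "current",
) -> EconResult:
    """Full output-value comparison across planting scenarios."""
    if baseline not in scenarios:
        raise ValidationError(f"baseline scenario {baseline!r} not among {sorted(scenarios)}")
    crops = list(scenarios[baseline].proportions)
    rows = {c: {"crop": c} for c in crops}
    totals: dict[str, float] = {}
    for name, scen in scenarios.items():
        areas = scenario_areas(scen, total_cultivated)
        totals[name] = total_net_output(econ, areas)
        for c in crops:
            rec = econ[c]
            unit = unit_net_output(rec.yield_kg_hm2, rec.price_yuan_kg, rec.unit_input_yuan_hm2)
            rows[c]["unit_net_output_yuan_hm2"] = unit
            rows[c][f"area_{name}_hm2"] = areas[c]
            rows[c][f"net_output_{name}_Myuan"] = round_half_up(unit * areas[c] / 1e6, 2)
    pct = {
        name: scenario_econ_compare(totals[baseline], t)
        for name, t in totals.items()
        if name != baseline
    }
    return EconResult(table=pd.DataFrame(list(rows.values())), totals=totals, pct_change=pct)
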