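"""Techno-economic scaling/payback arithmetic and emission accounting.

Plant economics scale with capacity through a power law
``cost = reference_cost * (capacity / reference_capacity)^alpha`` with
capacity index ``alpha = 0.65``.  Payback is the discounted break-even
time of a capital outlay against a constant annual operating saving
(8 % discount rate, 10-year lifetime by default).  Carbon accounting
multiplies avoided electricity through a regional grid emission factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EconScenario",
    "EmissionScenario",
    "EMISSION_SCENARIOS",
    "scale_cost",
    "discounted_payback",
    "annual_saving",
    "carbon_reduction",
    "npv_of_savings",
    "payback_sensitivity",
]


@dataclass(frozen=True)
class EconScenario:
    """Economic setting of an assisted-operation retrofit."""

    capex: float  # USD, user-supplied capital cost of the retrofit
    operating_saving: float = 13.5  # USD per tonne treated
    capacity: float = 100.0  # t/d
    reference_capacity: float = 30.0  # t/d
    capacity_index: float = 0.65  # alpha
    discount_rate: float = 0.08
    lifetime: int = 10  # years
    electricity_price: float = 0.10  # USD/kWh (0.08-0.12 band)
    feedstock_cost: float = 30.0  # USD/t (25-35 band)
    uptime_days: int = 330

    def __post_init__(self) -> None:
        positive = (
            self.capex,
            self.operating_saving,
            self.capacity,
            self.reference_capacity,
            self.capacity_index,
            self.lifetime,
            self.electricity_price,
            self.feedstock_cost,
            self.uptime_days,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("economic scenario fields must be positive")
        if not 0.0 < self.discount_rate < 1.0:
            raise ValueError("discount_rate must lie in (0, 1)")


@dataclass(frozen=True)
class EmissionScenario:
    """Regional grid emission factor and relative savings rates."""

    region: str
    grid_factor: float  # kg CO2 per kWh
    energy_savings_rate: float  # fraction of baseline electricity use avoided
    baseline_energy_intensity: float  # kWh per tonne treated, user-supplied

    def __post_init__(self) -> None:
        if self.grid_factor <= 0:
            raise ValueError("grid_factor must be positive")
        if not 0.0 <= self.energy_savings_rate <= 1.0:
            raise ValueError("energy_savings_rate must lie in [0, 1]")
        if self.baseline_energy_intensity <= 0:
            raise ValueError("baseline_energy_intensity must be positive")


def _emission_presets(intensity: float = 100.0) -> tuple[EmissionScenario, ...]:
    return (
        EmissionScenario("China", 0.65, 0.08, intensity),
        EmissionScenario("EU", 0.35, 0.09, intensity),
        EmissionScenario("USA", 0.45, 0.10, intensity),
    )


#: the three regional grid scenarios (default 100 kWh/t baseline intensity)
EMISSION_SCENARIOS = _emission_presets()


def scale_cost(
    reference_cost: float,
    reference_capacity: float,
    capacity: float,
    alpha: float = 0.65,
) -> float:
    """Power-law capacity scaling ``cost * (capacity / reference)^alpha``."""
    if min(reference_cost, reference_capacity, capacity, alpha) <= 0:
        raise ValueError("scale_cost arguments must be positive")
    return reference_cost * (capacity / reference_capacity) ** alpha


def discounted_payback(
    capex: float,
    annual_saving: float,
    discount_rate: float = 0.08,
    lifetime: int = 10,
) -> float | None:
    """Discounted break-even time in years, or None if never reached.

    The smallest t with ``sum_{i=1..t} saving / (1+r)^i >= capex``,
    linearly interpolated inside the crossing year.
    """
    if capex <= 0 or annual_saving <= 0:
        raise ValueError("capex and annual_saving must be positive")
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    cumulative = 0.0
    for year in range(1, int(lifetime) + 1):
        pv = annual_saving / (1.0 + discount_rate) ** year
        if cumulative + pv >= capex:
            return (year - 1) + (capex - cumulative) / pv
        cumulative += pv
    return None


def annual_saving(
    operating_saving: float, capacity: float, uptime_days: int = 330
) -> float:
    """Annual operating saving, USD/year = USD/t x t/d x uptime days."""
    if operating_saving < 0 or capacity < 0 or uptime_days <= 0:
        raise ValueError("inputs must be non-negative (uptime positive)")
    return operating_saving * capacity * uptime_days


def npv_of_savings(
    annual: float, discount_rate: float = 0.08, lifetime: int = 10
) -> float:
    """Present value of the saving stream over the equipment lifetime."""
    years = np.arange(1, int(lifetime) + 1)
    return float(np.sum(annual / (1.0 + discount_rate) ** years))


def carbon_reduction(
    scenario: EmissionScenario, throughput: float
) -> tuple[float, float]:
    """(energy saved kWh/y, CO2 avoided kg/y) for an annual throughput in t/y."""
    if throughput < 0:
        raise ValueError("throughput must be >= 0")
    energy_saved = scenario.baseline_energy_intensity * throughput * scenario.energy_savings_rate
    return energy_saved, energy_saved * scenario.grid_factor


def payback_sensitivity(
    capex: float,
    capacity: float = 100.0,
    operating_savings=(12.0, 13.0, 14.0, 15.0),
    discount_rates=(0.06, 0.08, 0.10),
    lifetime: int = 10,
    uptime_days: int = 330,
) -> pd.DataFrame:
    """Tabular payback sweep over operating saving x discount rate."""
    rows = []
    for saving, rate in itertools.product(operating_savings, discount_rates):
        annual = annual_saving(saving, capacity, uptime_days)
        rows.append(
            {
                "operating_saving": saving,
                "discount_rate": rate,
                "annual_saving": annual,
                "npv_savings": npv_of_savings(annual, rate, lifetime),
                "payback_years": discounted_payback(capex, annual, rate, lifetime),
            }
        )
    return pd.DataFrame(rows)
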