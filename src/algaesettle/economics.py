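"""Harvesting cost model: centrifugation (energy) vs. sedimentation (consumables).

Costs are tracked per cubic metre of culture and converted to cost per
kilogram of recovered dry biomass through the harvested concentration:
1 mg/L == 1 g/m^3, so the culture volume needed for a kilogram of biomass is
1000 / harvested(mg/L) m^3.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HarvestCostInputs",
    "HarvestCost",
    "cost_per_m3",
    "harvested_biomass",
    "cost_per_kg",
    "percent_reduction",
]


@dataclass(frozen=True)
class HarvestCostInputs:
    method: str  # "centrifugation" or "sedimentation"
    dry_weight_mg_per_l: float
    recovery_pct: float
    energy_kwh_per_m3: float = 0.0
    energy_rate_usd_per_kwh: float = 0.0
    consumables_usd_per_m3: float = 0.0

    def __post_init__(self) -> None:
        vals = (
            self.dry_weight_mg_per_l,
            self.recovery_pct,
            self.energy_kwh_per_m3,
            self.energy_rate_usd_per_kwh,
            self.consumables_usd_per_m3,
        )
        if any(v < 0 for v in vals):
            raise ValueError("cost inputs must be non-negative")
        if self.recovery_pct > 100:
            raise ValueError("recovery_pct cannot exceed 100")


@dataclass(frozen=True)
class HarvestCost:
    method: str
    cost_per_m3_usd: float
    harvested_mg_per_l: float
    volume_per_kg_m3: float
    cost_per_kg_usd: float


def cost_per_m3(inputs: HarvestCostInputs) -> float:
    """Operating cost per m^3: energy * rate + consumables."""
    return (
        inputs.energy_kwh_per_m3 * inputs.energy_rate_usd_per_kwh
        + inputs.consumables_usd_per_m3
    )


def harvested_biomass(dry_weight_mg_per_l: float, recovery_pct: float) -> float:
    """Recovered dry biomass concentration, mg/L."""
    if dry_weight_mg_per_l < 0 or recovery_pct < 0:
        raise ValueError("inputs must be non-negative")
    return dry_weight_mg_per_l * recovery_pct / 100.0


def cost_per_kg(inputs: HarvestCostInputs) -> HarvestCost:
    """Full cost chain: $/m^3 -> volume per kg -> $/kg of dry biomass."""
    harvested = harvested_biomass(inputs.dry_weight_mg_per_l, inputs.recovery_pct)
    if harvested <= 0:
        raise ValueError("harvested biomass must be > 0 to cost per kg")
    volume_per_kg = 1000.0 / harvested  # mg/L == g/m^3; 1 kg = 1000 g
    c_m3 = cost_per_m3(inputs)
    return HarvestCost(
        method=inputs.method,
        cost_per_m3_usd=c_m3,
        harvested_mg_per_l=harvested,
        volume_per_kg_m3=volume_per_kg,
        cost_per_kg_usd=c_m3 * volume_per_kg,
    )


def percent_reduction(cost_ref: float, cost_new: float) -> float:
    """Relative saving of the new method vs. the reference, in percent."""
    if cost_ref <= 0:
        raise ValueError("reference cost must be > 0")
    return 100.0 * (cost_ref - cost_new) / cost_ref
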