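"""CDR discounts from biomass shipping and BECCS CO2 capture losses.

A harvested tonne of wet biomass carries 54,300 g of carbon (~200 kg CO2
fixed).  Bulk carriers emit 2.7-33.9 g CO2 per tonne-km depending on vessel
size, and post-combustion CO2 separation captures only 80-90% of the flue
gas.  Both offsets are expressed as percent of the theoretical CDR; harvest,
drying and loading emissions are excluded (a deliberate lower bound).
"""

from __future__ import annotations

from dataclasses import dataclass

from seaweed_cdr.carbonate import M_C, M_CO2, DomainError

__all__ = [
    "VESSEL_EMISSION_FACTORS",
    "LogisticsScenario",
    "shipping_discount",
    "beccs_discount",
]

#: bulk-carrier emission endpoints, g CO2 per t cargo per km
VESSEL_EMISSION_FACTORS = {"small": 33.9, "large": 2.7}


@dataclass(frozen=True)
class LogisticsScenario:
    """Shipping + capture scenario.

    ``emission_factor`` in g CO2 t-1 km-1 (2.7-33.9 spans bulk-carrier
    sizes), ``distance`` in km, ``carbon_per_tonne_ww`` in g C per tonne
    wet weight, ``capture_efficiency`` the CO2 separation fraction.
    """

    emission_factor: float = VESSEL_EMISSION_FACTORS["small"]
    distance: float = 100.0
    carbon_per_tonne_ww: float = 54_300.0
    capture_efficiency: float = 0.9

    def __post_init__(self) -> None:
        if self.emission_factor <= 0:
            raise DomainError("emission_factor must be > 0")
        if self.distance < 0:
            raise DomainError("distance must be >= 0")
        if self.carbon_per_tonne_ww <= 0:
            raise DomainError("carbon_per_tonne_ww must be > 0")
        if not 0.0 < self.capture_efficiency <= 1.0:
            raise DomainError(
                f"capture_efficiency {self.capture_efficiency} outside (0, 1]")


def shipping_discount(scenario: LogisticsScenario) -> dict[str, float]:
    """Shipping CO2 offset as percent of fixed CO2.

    Returns the per-km rate (% t-ww-1 km-1) and the total at the scenario
    distance; the denominator is the CO2 equivalent of the carbon carried
    per tonne wet weight.
    """
    co2_per_tonne = scenario.carbon_per_tonne_ww * M_CO2 / M_C
    per_km = scenario.emission_factor / co2_per_tonne * 100.0
    return {"percent_per_km": per_km,
            "percent_at_distance": per_km * scenario.distance}


def beccs_discount(capture_efficiency: float) -> float:
    """CO2 lost in flue-gas separation, percent of CDR."""
    if not 0.0 < capture_efficiency <= 1.0:
        raise DomainError(
            f"capture_efficiency {capture_efficiency} outside (0, 1]")
    return (1.0 - capture_efficiency) * 100.0
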