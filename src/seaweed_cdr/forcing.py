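"""Albedo radiative forcing of floating seaweed versus CDR forcing.

Floating rafts brighten the sea surface.  The daily reduction in absorbed
shortwave is

    dRF_daily = Qs_down * delta_a * (1 - alpha_atm)        [J m-2 d-1]

accumulated over the monthly coverage series to a yearly total (PJ/y).  The
competing greenhouse benefit of removing carbon is the logarithmic CO2
forcing spread over the Earth's surface, expressed per tonne of carbon and
per year; dividing the albedo total by the per-cycle CDR forcing gives the
number of annual growth cycles after which cumulative CDR outweighs the
(constant) albedo effect.

Sign convention: reductions in radiative forcing are returned as negative
numbers (the albedo and CDR effects both cool); crossover arithmetic uses
their magnitudes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from seaweed_cdr.carbonate import DomainError

__all__ = [
    "SECONDS_PER_DAY",
    "EARTH_SURFACE_M2",
    "TONNES_C_PER_PPM",
    "CO2_FORCING_COEFF",
    "ForcingScenario",
    "wm2_to_daily",
    "rf_daily",
    "rf_yearly",
    "rf_per_tonne_carbon",
    "cdr_forcing_per_cycle",
    "crossover_cycles",
]

SECONDS_PER_DAY = 86_400.0
DAYS_PER_YEAR = 365.0
EARTH_SURFACE_M2 = 510e12
#: tonnes of carbon per 1 ppmv of atmospheric CO2
TONNES_C_PER_PPM = 2.124e9
#: logarithmic CO2 radiative forcing coefficient, W m-2
CO2_FORCING_COEFF = 5.35


@dataclass(frozen=True)
class ForcingScenario:
    """Monthly albedo-forcing scenario.

    ``solar_flux`` is the downward shortwave at the site in W/m² per month
    (converted internally to J m-2 d-1); ``coverage`` the raft area in km²
    per month; ``months`` ISO year-month labels aligned with both.
    ``delta_albedo`` is the raft-minus-water albedo increase (seagrass
    canopies suggest 0.01-0.07; surface rafts sit at or above the top of
    that range) and ``alpha_atm`` the shortwave fraction absorbed by the
    atmosphere before reaching the surface.
    """

    months: tuple[str, ...]
    solar_flux: tuple[float, ...]
    coverage: tuple[float, ...]
    delta_albedo: float = 0.1
    alpha_atm: float = 0.2
    c_atm: float = 410.0

    def __post_init__(self) -> None:
        if not (len(self.months) == len(self.solar_flux)
                == len(self.coverage)):
            raise ValueError(
                "months, solar_flux and coverage must have equal length")
        if len(self.months) < 12:
            raise ValueError("scenario needs at least 12 months")
        if not 0.0 <= self.delta_albedo <= 1.0:
            raise DomainError(f"delta_albedo {self.delta_albedo} outside [0, 1]")
        if not 0.0 <= self.alpha_atm < 1.0:
            raise DomainError(f"alpha_atm {self.alpha_atm} outside [0, 1)")
        if any(q <= 0 for q in self.solar_flux):
            raise DomainError("solar_flux must be strictly positive")
        if any(a < 0 for a in self.coverage):
            raise DomainError("coverage must be >= 0")
        if self.c_atm <= 0:
            raise DomainError(f"c_atm {self.c_atm} ppm must be > 0")


def wm2_to_daily(flux_wm2):
    """W/m² -> J m-2 d-1 (x 86,400)."""
    return np.asarray(flux_wm2, dtype=float) * SECONDS_PER_DAY


def rf_daily(qs_down: float, delta_albedo: float,
             alpha_atm: float = 0.2) -> float:
    """Daily surface shortwave reduction, J m-2 d-1 (returned negative).

    ``qs_down`` in J m-2 d-1.
    """
    if not 0.0 <= delta_albedo <= 1.0:
        raise DomainError(f"delta_albedo {delta_albedo} outside [0, 1]")
    if not 0.0 <= alpha_atm < 1.0:
        raise DomainError(f"alpha_atm {alpha_atm} outside [0, 1)")
    if qs_down <= 0:
        raise DomainError("qs_down must be strictly positive")
    return -qs_down * delta_albedo * (1.0 - alpha_atm)


def rf_yearly(scenario: ForcingScenario) -> float:
    """Yearly albedo forcing reduction over the coverage series, PJ/y.

    Sums monthly dRF_daily x calendar days x covered area.  Negative
    (a cooling); linear in delta_albedo and in uniform coverage scaling.
    """
    total_j = 0.0
    for month, flux, cov_km2 in zip(scenario.months, scenario.solar_flux,
                                    scenario.coverage):
        days = pd.Period(month, freq="M").days_in_month
        daily = rf_daily(wm2_to_daily(flux), scenario.delta_albedo,
                         scenario.alpha_atm)
        total_j += daily * days * cov_km2 * 1e6
    return total_j / 1e15


def rf_per_tonne_carbon(c_atm: float = 410.0) -> float:
    """Yearly forcing reduction from removing 1 t C, GJ tC-1 y-1 (negative).

    Logarithmic CO2 forcing (5.35 W/m² per e-fold) over the Earth surface;
    2.124e9 t C raise the atmosphere by 1 ppmv.
    """
    if c_atm <= 0:
        raise DomainError(f"c_atm {c_atm} ppm must be > 0")
    # ln((c + dc)/c) with dc ~ 5e-10 ppm loses ~4 digits if formed directly;
    # log1p keeps the one-tonne perturbation exact
    joules = (SECONDS_PER_DAY * DAYS_PER_YEAR * CO2_FORCING_COEFF
              * math.log1p(1.0 / (TONNES_C_PER_PPM * c_atm))
              * EARTH_SURFACE_M2)
    return -joules / 1e9


def cdr_forcing_per_cycle(cdr_tonnes_c: float, c_atm: float = 410.0) -> float:
    """Forcing reduction from one growth cycle's CDR, PJ/y (negative)."""
    if cdr_tonnes_c < 0:
        raise DomainError("cdr_tonnes_c must be >= 0")
    return rf_per_tonne_carbon(c_atm) * cdr_tonnes_c * 1e9 / 1e15


def crossover_cycles(rf_yearly_albedo: float, cdr_per_cycle_tonnes: float,
                     c_atm: float = 410.0) -> float:
    """Growth cycles until cumulative CDR forcing matches the albedo effect.

    Assumes the albedo forcing is constant while CDR forcing accumulates
    linearly cycle over cycle with instantaneous air-sea CO2 transfer and a
    fixed atmospheric concentration.  Accepts the albedo term with either
    sign (magnitude is used).  Zero CDR returns +inf with a warning.
    """
    if cdr_per_cycle_tonnes == 0:
        warnings.warn("zero CDR per cycle: albedo effect is never outweighed",
                      stacklevel=2)
        return math.inf
    per_cycle = abs(cdr_forcing_per_cycle(cdr_per_cycle_tonnes, c_atm))
    return abs(rf_yearly_albedo) / per_cycle
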