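"""Air-sea CO2 equilibration timescales.

After photosynthesis draws CO2 out of the mixed layer, the deficit is only
refilled from the atmosphere on the timescale

    tau_CO2 = h * DIC / (G * B * [CO2*]) = h / (G * B * R)

with h the mixed-layer depth (m), R = [CO2*]/DIC the dissolved-CO2 fraction
of DIC, G the gas transfer velocity (m/s) and B the Revelle factor: a DIC
perturbation decays at rate G*B*R/h because only the dissolved-CO2 sliver
of the deficit, amplified B-fold in pCO2, is exposed to gas exchange.  Comparing tau_CO2
with the residence time of water in the mixed layer (tau_res, an input
field from a circulation model) indicates whether afforested water can lose
atmospheric contact before its CO2 deficit is replenished -- the central
verification challenge for open-ocean afforestation CDR.

Three entry points: the scalar identity (:func:`tau_co2`), factorial
scenario sweeps (:func:`scenario_table`), and gridded monthly fields
(:func:`tau_map`, :func:`region_summary`).  A "month" is 365/12 days.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from seaweed_cdr.carbonate import (
    DomainError,
    SeawaterConditions,
    _alkalinity,
    _bisect_ph,
    _carbonate_alkalinity_from_co2,
    _constants,
    dic_from_ta_pco2,
    gas_transfer_velocity,
    solve_carbonate_system,
)

__all__ = [
    "SECONDS_PER_MONTH",
    "SEASONS",
    "tau_co2",
    "scenario_table",
    "solve_rb_fields",
    "tau_map",
    "region_summary",
]

#: 365/12 days expressed in seconds.
SECONDS_PER_MONTH = 365.0 / 12.0 * 86400.0

SEASONS = {
    "annual": (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12),
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}

#: variables a gridded field set must carry (CF-ish short names).
REQUIRED_FIELDS = ("ta", "pco2", "tos", "sos", "mld", "u10", "tau_res")


def tau_co2(h, r, g, b):
    """Equilibration timescale in months from its four components.

    ``r`` is the dissolved-CO2 fraction [CO2*]/DIC; the timescale scales
    with its inverse (the DIC pool is DIC/[CO2*] times larger than the part
    gas exchange acts on).  Accepts scalars or broadcastable arrays; every
    component must be strictly positive.
    """
    for name, val in (("h", h), ("r", r), ("g", g), ("b", b)):
        if np.any(np.asarray(val) <= 0):
            raise DomainError(f"tau_co2 component {name!r} must be > 0")
    tau = np.asarray(h, dtype=float) / (np.asarray(g, dtype=float) * b * r)
    tau = tau / SECONDS_PER_MONTH
    if all(np.ndim(v) == 0 for v in (h, r, g, b)):
        return float(tau)
    return tau


def scenario_table(h_values: Sequence[float], t_values: Sequence[float],
                   u10_values: Sequence[float], ta: float = 2350.0,
                   pco2_eq: float = 410.0, salinity: float = 35.0
                   ) -> pd.DataFrame:
    """Full-factorial tau_CO2 sweep over mixed-layer depth, T and wind.

    DIC at each temperature is derived from (TA, equilibrated pCO2) by
    inverting the carbonate solver; R and B follow from the solved state.
    Returns one row per (h, T, u10) combination with all components.
    """
    if not (len(h_values) and len(t_values) and len(u10_values)):
        raise ValueError("scenario value lists must be non-empty")
    rows = []
    for t in t_values:
        cond = SeawaterConditions(salinity=salinity, temperature=t)
        dic = dic_from_ta_pco2(ta, pco2_eq, cond)
        sp = solve_carbonate_system(ta, dic, cond)
        for u in u10_values:
            g = gas_transfer_velocity(u, t)
            for h in h_values:
                rows.append({
                    "h_m": h, "temperature_c": t, "u10_ms": u,
                    "dic_umol_kg": dic, "r_ratio": sp.r_ratio,
                    "revelle_b": sp.revelle_b, "g_ms": g,
                    "tau_co2_months": tau_co2(h, sp.r_ratio, g, sp.revelle_b),
                })
    return pd.DataFrame(rows)


def solve_rb_fields(ta, pco2, tos, sos, phosphate=0.0, silicate=0.0):
    """Vectorised R (CO2*/DIC) and Revelle B from TA/pCO2/T/S arrays.

    NaNs are propagated: cells with any missing input come back NaN.
    DIC is derived from (TA, pCO2); B by central finite difference in DIC
    (1 µmol/kg) at constant TA.
    """
    ta = np.asarray(ta, dtype=float)
    pco2 = np.asarray(pco2, dtype=float)
    tos = np.asarray(tos, dtype=float)
    sos = np.asarray(sos, dtype=float)
    tp = np.asarray(phosphate, dtype=float) * 1e-6
    tsi = np.asarray(silicate, dtype=float) * 1e-6

    mask = ~(np.isfinite(ta) & np.isfinite(pco2) & np.isfinite(tos)
             & np.isfinite(sos))
    # benign placeholder values under the mask keep the solver happy
    ta_f = np.where(mask, 2350.0, ta)
    pco2_f = np.where(mask, 410.0, pco2)
    tos_f = np.where(mask, 25.0, tos)
    sos_f = np.where(mask, 35.0, sos)
    tp_f = np.where(np.isfinite(tp), tp, 0.0)
    tsi_f = np.where(np.isfinite(tsi), tsi, 0.0)

    k = _constants(sos_f, tos_f)
    co2 = k.k0 * pco2_f * 1e-6  # mol/kg

    def ph_from_co2(co2_mol):
        def residual(ph):
            hh = 10.0 ** (-np.asarray(ph, dtype=float))
            ca = _carbonate_alkalinity_from_co2(hh, co2_mol, k)
            other = _alkalinity(hh, np.zeros_like(hh + ta_f), k, tp_f, tsi_f)
            return ca + other - ta_f * 1e-6

        return _bisect_ph(residual)

    h_ion = 10.0 ** -ph_from_co2(co2)
    dic = co2 * (1.0 + k.k1 / h_ion + k.k1 * k.k2 / (h_ion * h_ion))
    r = co2 / dic

    # Revelle factor: perturb DIC at constant TA, re-solve pH
    d = 1e-6  # 1 µmol/kg

    def co2_at_dic(dic_mol):
        def residual(ph):
            hh = 10.0 ** (-np.asarray(ph, dtype=float))
            return _alkalinity(hh, dic_mol, k, tp_f, tsi_f) - ta_f * 1e-6

        hh = 10.0 ** -_bisect_ph(residual)
        return dic_mol * hh * hh / (hh * hh + k.k1 * hh + k.k1 * k.k2)

    b = (co2_at_dic(dic + d) - co2_at_dic(dic - d)) / (2 * d) * dic / co2

    r = np.where(mask, np.nan, r)
    b = np.where(mask, np.nan, b)
    dic_umol = np.where(mask, np.nan, dic * 1e6)
    return r, b, dic_umol


def _season_mean(da: xr.DataArray, months: tuple[int, ...]) -> xr.DataArray:
    return da.sel(time=da["time"].dt.month.isin(list(months))).mean(
        "time", skipna=False)


def tau_map(fields: xr.Dataset, season: str = "annual") -> xr.Dataset:
    """Gridded tau_CO2 and its ratio to tau_res.

    ``fields`` must carry monthly ``ta`` (µmol/kg), ``pco2`` (µatm), ``tos``
    (°C), ``sos``, ``mld`` (m), ``u10`` (m/s) and ``tau_res`` (months) on
    shared lat/lon/time axes (``phosphate``/``silicate`` optional, µmol/kg).
    Components (h, R, G, B) are averaged over the season's months first and
    tau computed from the averaged components; cells with any missing input
    are NaN in the output.
    """
    missing = [v for v in REQUIRED_FIELDS if v not in fields]
    if missing:
        raise ValueError(f"gridded field set lacks variables: {missing}")
    for v in REQUIRED_FIELDS:
        if fields[v].dims != fields["ta"].dims:
            raise ValueError(
                f"field {v!r} dims {fields[v].dims} != {fields['ta'].dims}")
    if season not in SEASONS:
        raise ValueError(f"season {season!r} not one of {sorted(SEASONS)}")
    months = SEASONS[season]

    mean = {
        v: _season_mean(fields[v], months)
        for v in ("ta", "pco2", "tos", "sos", "mld", "u10")
    }
    for v in ("phosphate", "silicate"):
        mean[v] = (_season_mean(fields[v], months) if v in fields
                   else xr.zeros_like(mean["ta"]))
    tau_res = _season_mean(fields["tau_res"], months)

    r, b, dic = solve_rb_fields(mean["ta"].values, mean["pco2"].values,
                                mean["tos"].values, mean["sos"].values,
                                mean["phosphate"].values,
                                mean["silicate"].values)
    with np.errstate(invalid="ignore"):
        sc_ok = np.clip(mean["tos"].values, -2.0, 40.0)
        g = 0.251 * mean["u10"].values ** 2 * (
            (2116.8 - 136.25 * sc_ok + 4.7353 * sc_ok ** 2
             - 0.092307 * sc_ok ** 3 + 0.0007555 * sc_ok ** 4) / 660.0
        ) ** -0.5 / 360000.0
        h = mean["mld"].values
        tau = h / (g * b * r) / SECONDS_PER_MONTH
        ratio = tau / tau_res.values

    coords = mean["ta"].coords
    out = xr.Dataset(
        {
            "tau_co2": (mean["ta"].dims, tau),
            "tau_res": (mean["ta"].dims, tau_res.values),
            "ratio": (mean["ta"].dims, ratio),
            "h": (mean["ta"].dims, h),
            "r_ratio": (mean["ta"].dims, r),
            "g": (mean["ta"].dims, g),
            "revelle_b": (mean["ta"].dims, b),
            "dic": (mean["ta"].dims, dic),
        },
        coords=coords,
        attrs={"season": season,
               "description": "air-sea CO2 equilibration timescale (months) "
                              "and ratio to mixed-layer residence time"},
    )
    out["tau_co2"].attrs["units"] = "months"
    out["tau_res"].attrs["units"] = "months"
    return out


def region_summary(result: xr.Dataset, mask: xr.DataArray | None = None,
                   cos_lat_weight: bool = False) -> pd.DataFrame:
    """Min/mean/max of tau_CO2, tau_res and their ratio over selected cells.

    ``mask`` (boolean, same grid) restricts the region; statistics are
    unweighted unless ``cos_lat_weight`` applies cosine-latitude weights to
    the mean.  Raises if the selection holds no valid cell.
    """
    rows = {}
    for var in ("tau_co2", "tau_res", "ratio"):
        da = result[var]
        if mask is not None:
            da = da.where(mask)
        valid = da.notnull()
        if int(valid.sum()) == 0:
            raise ValueError(f"region selection empty for {var!r}")
        if cos_lat_weight:
            w = np.cos(np.deg2rad(da["lat"])).broadcast_like(da)
            mean = float(da.weighted(w.where(valid, 0.0)).mean())
        else:
            mean = float(da.mean())
        rows[var] = {"min": float(da.min()), "mean": mean,
                     "max": float(da.max()),
                     "n_cells": int(valid.sum())}
    return pd.DataFrame(rows).T
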