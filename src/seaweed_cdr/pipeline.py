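"""Orchestration: one config in, a consolidated report bundle out.

Runs the full afforestation-analog analysis -- carbonate kernel, four-term
budget with bounds and DOC, gridded equilibration timescales, albedo
forcing with crossover, logistics discounts -- and writes CSV tables plus a
single machine-readable ``report.json`` holding every headline number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from seaweed_cdr import budget as bd
from seaweed_cdr import equilibration as eq
from seaweed_cdr import forcing as fo
from seaweed_cdr import logistics as lg
from seaweed_cdr import synth as sy
from seaweed_cdr.carbonate import SeawaterConditions, solve_carbonate_system

__all__ = ["AnalysisConfig", "run_full_analysis"]

log = logging.getLogger("seaweed_cdr")


@dataclass
class AnalysisConfig:
    """Inputs for :func:`run_full_analysis`.

    File paths may be ``None``, in which case seeded synthetic stand-ins are
    generated.  Seawater conditions and TA/DIC defaults are the subtropical
    reference state used for the central psi.
    """

    biomass_csv: str | None = None
    fields_netcdf: str | None = None
    seed: int = 0
    ta: float = 2350.0
    dic: float = 2047.5
    salinity: float = 35.0
    temperature: float = 25.0
    limiting: str = "N"
    delta_albedo_values: tuple[float, ...] = (0.01, 0.05, 0.1)
    alpha_atm: float = 0.2
    c_atm: float = 410.0
    shipping_distance_km: float = 100.0
    capture_efficiency: float = 0.9
    season: str = "annual"
    stoichiometry: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "delta_albedo_values" in raw:
            raw["delta_albedo_values"] = tuple(raw["delta_albedo_values"])
        return cls(**raw)

    def params(self) -> bd.StoichiometryParams:
        overrides = dict(self.stoichiometry)
        for key in ("caco3_ww_range", "seaweed_cn_range"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return bd.StoichiometryParams(**overrides)


def _load_inputs(config: AnalysisConfig):
    spec = sy.SynthSpec(seed=config.seed)
    if config.biomass_csv is not None:
        path = Path(config.biomass_csv)
        if not path.exists():
            raise FileNotFoundError(f"biomass series not found: {path}")
        series = bd.read_biomass_csv(path)
    else:
        series = sy.synth_biomass_series(spec)
    if config.fields_netcdf is not None:
        import xarray as xr

        path = Path(config.fields_netcdf)
        if not path.exists():
            raise FileNotFoundError(f"gridded fields not found: {path}")
        fields = xr.open_dataset(path, engine="scipy")
    else:
        fields = sy.synth_gridded_fields(spec)
    flux = sy.synth_solar_flux(spec)
    return series, fields, flux


def run_full_analysis(config: AnalysisConfig, out_dir) -> dict:
    """Execute every stage and write the report bundle into ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).  Any
    stage failure raises with the stage name; nothing is written in that
    case.
    """
    out = Path(out_dir)
    params = config.params()
    cond = SeawaterConditions(salinity=config.salinity,
                              temperature=config.temperature)
    series, fields, flux = _load_inputs(config)

    report: dict = {"config": {k: v for k, v in asdict(config).items()}}
    try:
        stage = "carbonate"
        sp = solve_carbonate_system(config.ta, config.dic, cond)
        log.debug("carbonate state: %s", sp)
        report["carbonate"] = {
            "psi": sp.psi, "revelle_b": sp.revelle_b, "r_ratio": sp.r_ratio,
            "ph": sp.ph, "pco2_uatm": sp.pco2,
        }

        stage = "budget"
        peak_ww = max(r.wet_weight for r in series)
        partition = bd.partition_carbon(peak_ww, params)
        nutrients = bd.nutrient_uptake(peak_ww, params)
        budget = bd.budget_from_wet_weight(peak_ww, sp.psi, params,
                                           config.limiting)
        bounds = bd.propagate_bounds(params, partition.tpc_mol, sp.psi)
        doc = bd.doc_production(series, params)
        log.debug("stoichiometry: %s", params)
        report["budget"] = {
            "peak_wet_weight_mt": peak_ww,
            "tpc_mt": partition.tpc_mt,
            "poc_seaweed_mt": budget.poc_seaweed,
            "pic_seaweed_co2_mt": budget.pic_seaweed_co2,
            "poc_plankton_mt": budget.poc_plankton,
            "pic_plankton_co2_mt": budget.pic_plankton_co2,
            "cdr_theoretical_mt": budget.cdr_theoretical,
            "calcification_offset":
                bd.calcification_offset(partition, sp.psi),
            "nutrients_gmol": nutrients,
            "organic_cn": bd.organic_cn_ratio(partition, peak_ww, params),
            "organic_cp": bd.organic_cp_ratio(partition, peak_ww, params),
            "bound_lower_per100mol": bounds["lower"]["net"],
            "bound_upper_per100mol": bounds["upper"]["net"],
            "bound_lower_mt": bounds["lower"]["mt_c"],
            "bound_upper_mt": bounds["upper"]["mt_c"],
            "cdr_gt_co2": bd.to_gigatonnes_co2(budget.cdr_theoretical),
            "bound_lower_gt_co2": bd.to_gigatonnes_co2(bounds["lower"]["mt_c"]),
            "bound_upper_gt_co2": bd.to_gigatonnes_co2(bounds["upper"]["mt_c"]),
            "doc_production_mt": doc,
        }

        stage = "equilibration"
        tau = eq.tau_map(fields, season=config.season)
        summary = eq.region_summary(tau)
        report["equilibration"] = {var: dict(summary.loc[var])
                                   for var in ("tau_co2", "tau_res", "ratio")}
        report["equilibration"]["season"] = config.season

        stage = "forcing"
        coverage = [r.coverage for r in series[-12:]]
        months = [r.month for r in series[-12:]]
        rf_rows = []
        for da in config.delta_albedo_values:
            scen = fo.ForcingScenario(
                months=tuple(months), solar_flux=tuple(flux.values),
                coverage=tuple(coverage), delta_albedo=da,
                alpha_atm=config.alpha_atm, c_atm=config.c_atm)
            rfy = fo.rf_yearly(scen)
            rf_rows.append({
                "delta_albedo": da, "rf_yearly_pj": rfy,
                "crossover_cycles": fo.crossover_cycles(
                    rfy, budget.cdr_theoretical * 1e6, config.c_atm),
            })
        report["forcing"] = {
            "rf_per_tonne_c_gj": fo.rf_per_tonne_carbon(config.c_atm),
            "cdr_forcing_per_cycle_pj": fo.cdr_forcing_per_cycle(
                budget.cdr_theoretical * 1e6, config.c_atm),
            "scenarios": rf_rows,
        }

        stage = "logistics"
        ship_small = lg.shipping_discount(lg.LogisticsScenario(
            emission_factor=lg.VESSEL_EMISSION_FACTORS["small"],
            distance=config.shipping_distance_km))
        ship_large = lg.shipping_discount(lg.LogisticsScenario(
            emission_factor=lg.VESSEL_EMISSION_FACTORS["large"],
            distance=config.shipping_distance_km))
        report["logistics"] = {
            "shipping_small_vessel": ship_small,
            "shipping_large_vessel": ship_large,
            "beccs_loss_percent": lg.beccs_discount(config.capture_efficiency),
        }
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc

    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([report["budget"]]).T.to_csv(out / "budget.csv",
                                              header=["value"])
    summary.to_csv(out / "tau_summary.csv")
    pd.DataFrame(rf_rows).to_csv(out / "forcing.csv", index=False)
    pd.DataFrame([report["logistics"]["shipping_small_vessel"],
                  report["logistics"]["shipping_large_vessel"]],
                 index=["small_vessel", "large_vessel"]
                 ).to_csv(out / "logistics.csv")
    bd.write_biomass_csv(series, out / "biomass_series.csv")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("report bundle written to %s", out)
    return report
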