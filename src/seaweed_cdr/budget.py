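"""Wet-weight biomass to the theoretical CDR budget.

Converts satellite-derived Sargassum wet weight into its carbon partition
(total / organic / inorganic particulate carbon), applies the two
biogeochemical feedbacks -- epibiont calcification and nutrient reallocation
from phytoplankton -- and evaluates the four-term net removal

    CDR = POC_seaweed - psi*PIC_seaweed - POC_plankton + psi*PIC_plankton

where the PIC terms enter as CO2-equivalents (psi mol CO2 evaded per mol
CaCO3 precipitated).  Also provides the worst/best-case bound propagation on
a 100-mol-TPC basis, DOC production from release-rate incubations, and the
Mt C -> Gt CO2 conversion.

Units: biomass in Mt wet weight, carbon masses in Mt C, nutrient inventories
in Gmol, stoichiometric ratios in mol/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from seaweed_cdr.carbonate import M_C, M_CACO3, M_CO2, M_FE, M_N, M_P, DomainError

__all__ = [
    "BiomassRecord",
    "StoichiometryParams",
    "CarbonPartition",
    "CDRBudget",
    "read_biomass_csv",
    "write_biomass_csv",
    "wet_weight_to_tpc",
    "partition_carbon",
    "calcification_offset",
    "nutrient_uptake",
    "organic_cn_ratio",
    "organic_cp_ratio",
    "plankton_displacement",
    "reallocation_discount",
    "cdr_theoretical",
    "budget_from_wet_weight",
    "propagate_bounds",
    "doc_production",
    "to_gigatonnes_co2",
]

GRAMS_PER_MT = 1e12
MOL_PER_GMOL = 1e9


@dataclass(frozen=True)
class BiomassRecord:
    """One month of the satellite biomass series.

    ``month`` is an ISO year-month label ("2017-11"); ``wet_weight`` in Mt,
    ``coverage`` in km².
    """

    month: str
    wet_weight: float
    coverage: float = 0.0

    def __post_init__(self) -> None:
        pd.Period(self.month, freq="M")  # validates the label
        if self.wet_weight < 0:
            raise DomainError(f"wet_weight {self.wet_weight} Mt must be >= 0")
        if self.coverage < 0:
            raise DomainError(f"coverage {self.coverage} km² must be >= 0")

    @property
    def days_in_month(self) -> int:
        return pd.Period(self.month, freq="M").days_in_month


@dataclass(frozen=True)
class StoichiometryParams:
    """Stoichiometric conversion factors for the Sargassum raft community.

    Defaults are the central literature values for holopelagic Sargassum and
    (sub)tropical North Atlantic plankton; ranges carry the spread used for
    bound propagation.

    Attributes
    ----------
    tpc_per_ww : g C per g wet weight (total particulate carbon).
    caco3_ww_fraction : g CaCO3 per g wet weight from epibiont calcifiers
        (annual mean), with ``caco3_ww_range`` the single-sample spread.
    n_per_ww, p_per_ww, fe_per_ww : g element per g wet weight.
    seaweed_cn_range : admissible organic C:N (mol/mol) span of Sargassum.
    phyto_cn, phyto_cp : phytoplankton C:N and C:P (mol/mol).
    plankton_pic_poc : planktonic PIC:POC (mol/mol).
    doc_rate : DOC release, µg C per g wet weight per day (+/- doc_rate_sd).
    """

    tpc_per_ww: float = 0.0543
    caco3_ww_fraction: float = 0.094
    caco3_ww_range: tuple[float, float] = (0.043, 0.214)
    n_per_ww: float = 0.002
    p_per_ww: float = 0.0002
    fe_per_ww: float = 1.009e-5
    seaweed_cn_range: tuple[float, float] = (16.0, 108.0)
    phyto_cn: float = 8.0
    phyto_cp: float = 170.0
    plankton_pic_poc: float = 0.01
    doc_rate: float = 288.0
    doc_rate_sd: float = 24.0

    def __post_init__(self) -> None:
        for name in ("tpc_per_ww", "caco3_ww_fraction", "n_per_ww",
                     "p_per_ww", "fe_per_ww", "phyto_cn", "phyto_cp",
                     "doc_rate"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.plankton_pic_poc < 0:
            raise DomainError("plankton_pic_poc must be >= 0")
        if self.caco3_ww_fraction >= 1:
            raise DomainError("caco3_ww_fraction must be < 1 g/g")
        for name in ("caco3_ww_range", "seaweed_cn_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise DomainError(f"{name} must satisfy 0 < low <= high")

    def with_overrides(self, **kwargs) -> "StoichiometryParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CarbonPartition:
    """TPC split into organic (POC) and inorganic (PIC) carbon.

    Masses in Mt C (``caco3_mass`` in Mt CaCO3), amounts in mol.
    """

    tpc_mt: float
    pic_mt: float
    poc_mt: float
    tpc_mol: float
    pic_mol: float
    poc_mol: float
    pic_poc_ratio: float
    caco3_mass: float


@dataclass(frozen=True)
class CDRBudget:
    """The four-term theoretical CDR budget, all entries in Mt C.

    ``pic_seaweed_co2`` and ``pic_plankton_co2`` are CO2-equivalents
    (psi x PIC), not raw carbonate masses.
    """

    poc_seaweed: float
    pic_seaweed_co2: float
    poc_plankton: float
    pic_plankton_co2: float
    cdr_theoretical: float
    limiting_nutrient: str = "N"
    psi: float = float("nan")


def read_biomass_csv(path) -> list[BiomassRecord]:
    """Read a ``month,wet_weight_Mt,coverage_km2`` series."""
    df = pd.read_csv(path)
    required = {"month", "wet_weight_Mt", "coverage_km2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biomass CSV missing columns: {sorted(missing)}")
    return [
        BiomassRecord(month=str(r.month), wet_weight=float(r.wet_weight_Mt),
                      coverage=float(r.coverage_km2))
        for r in df.itertuples()
    ]


def write_biomass_csv(series: Sequence[BiomassRecord], path) -> None:
    pd.DataFrame(
        {"month": [r.month for r in series],
         "wet_weight_Mt": [r.wet_weight for r in series],
         "coverage_km2": [r.coverage for r in series]}
    ).to_csv(path, index=False)


def wet_weight_to_tpc(ww: float,
                      params: StoichiometryParams = StoichiometryParams()
                      ) -> float:
    """Total particulate carbon (Mt C) from wet weight (Mt)."""
    if ww < 0:
        raise DomainError(f"wet weight {ww} Mt must be >= 0")
    return ww * params.tpc_per_ww


def partition_carbon(ww: float,
                     params: StoichiometryParams = StoichiometryParams()
                     ) -> CarbonPartition:
    """Split wet weight into TPC, PIC and POC.

    PIC comes from the CaCO3 wet-weight fraction (CaCO3 at 100 g/mol); POC
    is the remainder of TPC.  Raises if the fraction is so large that PIC
    would exceed TPC (infeasible partition).
    """
    if ww < 0:
        raise DomainError(f"wet weight {ww} Mt must be >= 0")
    tpc_mt = wet_weight_to_tpc(ww, params)
    caco3_mt = ww * params.caco3_ww_fraction
    tpc_mol = tpc_mt * GRAMS_PER_MT / M_C
    pic_mol = caco3_mt * GRAMS_PER_MT / M_CACO3
    poc_mol = tpc_mol - pic_mol
    if ww > 0 and poc_mol <= 0:
        raise DomainError(
            f"CaCO3 fraction {params.caco3_ww_fraction} puts PIC "
            f"({pic_mol:.3g} mol) above TPC ({tpc_mol:.3g} mol): "
            "infeasible partition")
    ratio = pic_mol / poc_mol if poc_mol > 0 else 0.0
    return CarbonPartition(
        tpc_mt=tpc_mt, pic_mt=pic_mol * M_C / GRAMS_PER_MT,
        poc_mt=poc_mol * M_C / GRAMS_PER_MT,
        tpc_mol=tpc_mol, pic_mol=pic_mol, poc_mol=poc_mol,
        pic_poc_ratio=ratio, caco3_mass=caco3_mt,
    )


def calcification_offset(partition: CarbonPartition, psi: float) -> float:
    """Fraction of photosynthetic CO2 uptake undone by calcification.

    offset = PIC x psi / POC (mol basis).
    """
    if not 0 < psi < 1:
        raise DomainError(f"psi {psi} outside (0, 1)")
    if partition.poc_mol == 0:
        raise ZeroDivisionError("partition has zero POC")
    return partition.pic_mol * psi / partition.poc_mol


def nutrient_uptake(ww: float,
                    params: StoichiometryParams = StoichiometryParams()
                    ) -> dict[str, float]:
    """N, P, Fe bound in the biomass, in Gmol."""
    if ww < 0:
        raise DomainError(f"wet weight {ww} Mt must be >= 0")
    grams = ww * GRAMS_PER_MT
    return {
        "N": grams * params.n_per_ww / M_N / MOL_PER_GMOL,
        "P": grams * params.p_per_ww / M_P / MOL_PER_GMOL,
        "Fe": grams * params.fe_per_ww / M_FE / MOL_PER_GMOL,
    }


def organic_cn_ratio(partition: CarbonPartition, ww: float,
                     params: StoichiometryParams = StoichiometryParams()
                     ) -> float:
    """Organic (PIC-corrected) C:N of the raft community, mol/mol."""
    n_mol = ww * GRAMS_PER_MT * params.n_per_ww / M_N
    return partition.poc_mol / n_mol


def organic_cp_ratio(partition: CarbonPartition, ww: float,
                     params: StoichiometryParams = StoichiometryParams()
                     ) -> float:
    """Organic C:P of the raft community, mol/mol."""
    p_mol = ww * GRAMS_PER_MT * params.p_per_ww / M_P
    return partition.poc_mol / p_mol


def plankton_displacement(nutrients: Mapping[str, float], limiting: str,
                          params: StoichiometryParams, psi: float
                          ) -> dict[str, float]:
    """Foregone phytoplankton production from the reallocated nutrients.

    Returns ``poc_plankton`` (Mt C the plankton would have fixed with the
    limiting nutrient) and ``pic_plankton_co2`` (Mt C of CO2 the associated
    plankton calcification would have evaded, psi-weighted).
    """
    ratios = {"N": params.phyto_cn, "P": params.phyto_cp}
    if limiting not in ratios:
        raise ValueError(
            f"unknown limiting nutrient {limiting!r}; expected 'N' or 'P'")
    if limiting not in nutrients:
        raise ValueError(f"nutrient inventory lacks {limiting!r}")
    nutrient_mol = nutrients[limiting] * MOL_PER_GMOL
    poc_mol = nutrient_mol * ratios[limiting]
    pic_mol = poc_mol * params.plankton_pic_poc
    return {
        "poc_plankton": poc_mol * M_C / GRAMS_PER_MT,
        "pic_plankton_co2": pic_mol * psi * M_C / GRAMS_PER_MT,
    }


def reallocation_discount(seaweed_cn: float, phyto_cn: float) -> float:
    """Fraction of seaweed POC offset by foregone plankton fixation.

    Equals phyto C:N / seaweed C:N; exceeds 1 when the seaweed is no more
    nitrogen-efficient than the phytoplankton it displaces.
    """
    if seaweed_cn <= 0 or phyto_cn <= 0:
        raise DomainError("C:N ratios must be strictly positive")
    return phyto_cn / seaweed_cn


def cdr_theoretical(partition: CarbonPartition,
                    displacement: Mapping[str, float], psi: float,
                    limiting: str = "N") -> CDRBudget:
    """Assemble the four-term budget (all Mt C)."""
    pic_seaweed_co2 = partition.pic_mol * psi * M_C / GRAMS_PER_MT
    net = (partition.poc_mt - pic_seaweed_co2
           - displacement["poc_plankton"] + displacement["pic_plankton_co2"])
    return CDRBudget(
        poc_seaweed=partition.poc_mt,
        pic_seaweed_co2=pic_seaweed_co2,
        poc_plankton=displacement["poc_plankton"],
        pic_plankton_co2=displacement["pic_plankton_co2"],
        cdr_theoretical=net,
        limiting_nutrient=limiting,
        psi=psi,
    )


def budget_from_wet_weight(ww: float, psi: float,
                           params: StoichiometryParams = StoichiometryParams(),
                           limiting: str = "N") -> CDRBudget:
    """Wet weight -> full budget in one call (the central-case pipeline)."""
    partition = partition_carbon(ww, params)
    nutrients = nutrient_uptake(ww, params)
    displacement = plankton_displacement(nutrients, limiting, params, psi)
    return cdr_theoretical(partition, displacement, psi, limiting)


def _net_per_100mol_tpc(caco3_fraction: float, seaweed_cn: float,
                        params: StoichiometryParams, psi: float
                        ) -> dict[str, float]:
    """Evaluate the budget on a 100-mol-TPC basis.

    The PIC share of TPC follows from the CaCO3 wet-weight fraction and the
    TPC conversion factor; the nitrogen demand of the POC share follows from
    the prescribed seaweed C:N.
    """
    pic_per_tpc = (caco3_fraction / M_CACO3) / (params.tpc_per_ww / M_C)
    if pic_per_tpc >= 1:
        raise DomainError(
            f"CaCO3 fraction {caco3_fraction} infeasible: PIC would be "
            f"{100 * pic_per_tpc:.0f} mol per 100 mol TPC")
    pic = 100.0 * pic_per_tpc
    poc = 100.0 - pic
    poc_plankton = poc / seaweed_cn * params.phyto_cn
    pic_plankton = poc_plankton * params.plankton_pic_poc
    net = poc - pic * psi - poc_plankton + pic_plankton * psi
    return {"poc": poc, "pic_co2": pic * psi, "poc_plankton": poc_plankton,
            "pic_plankton_co2": pic_plankton * psi, "net": net}


def propagate_bounds(params: StoichiometryParams, tpc_mol: float, psi: float
                     ) -> dict[str, dict[str, float]]:
    """Worst/best-case net CDR per 100 mol TPC, scaled to Mt C.

    The lower bound pairs the highest CaCO3 fraction with the lowest
    seaweed C:N; the upper bound the reverse.  ``tpc_mol`` scales the
    per-100-mol nets to the bloom's Mt C.
    """
    f_lo, f_hi = params.caco3_ww_range
    cn_lo, cn_hi = params.seaweed_cn_range
    out = {}
    for name, frac, cn in (("lower", f_hi, cn_lo), ("upper", f_lo, cn_hi)):
        terms = _net_per_100mol_tpc(frac, cn, params, psi)
        terms["mt_c"] = terms["net"] / 100.0 * tpc_mol * M_C / GRAMS_PER_MT
        out[name] = terms
    return out


def doc_production(series: Iterable[BiomassRecord],
                   params: StoichiometryParams = StoichiometryParams()
                   ) -> float:
    """Cumulative DOC released over the series, Mt C.

    Each month contributes wet weight x release rate x calendar days.
    """
    records = list(series)
    if not records:
        raise ValueError("biomass series is empty")
    periods = [pd.Period(r.month, freq="M") for r in records]
    if any(b <= a for a, b in zip(periods, periods[1:])):
        raise ValueError("biomass series must be strictly chronological")
    total_g = sum(
        r.wet_weight * GRAMS_PER_MT * params.doc_rate * 1e-6 * r.days_in_month
        for r in records
    )
    return total_g / GRAMS_PER_MT


def to_gigatonnes_co2(cdr_mt_c: float) -> float:
    """Mt C -> Gt CO2 (x 44.009/12.011, / 1000)."""
    return cdr_mt_c * (M_CO2 / M_C) / 1000.0
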