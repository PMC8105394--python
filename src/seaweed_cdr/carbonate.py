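"""Seawater CO2-system kernel.

Solves the marine carbonate equilibrium from total alkalinity (TA) and
dissolved inorganic carbon (DIC) and derives the derived quantities the
afforestation budget and air-sea equilibration analyses need:

* ``psi`` -- mol CO2 released to solution per mol CaCO3 precipitated
  (Frankignoulle's calcification feedback ratio),
* the Revelle buffer factor ``B`` = (dpCO2/pCO2)/(dDIC/DIC) at constant TA,
* the dissolved-CO2 fraction ``R`` = [CO2*]/DIC,
* the CO2 Schmidt number and the quadratic-wind gas transfer velocity.

Equilibrium constants are pinned to the conventional "recommended" set for
open-ocean work: carbonic acid after Lueker, Dickson & Keeling (2000) on the
total pH scale, boric acid after Dickson (1990b), bisulfate after Dickson
(1990a), hydrogen fluoride after Perez & Fraga (1987), water after Millero
(1995), CO2 solubility after Weiss (1974), phosphoric and silicic acid after
Millero (1995), and Uppstrom (1974) total boron.  All concentrations are
mol/kg-solution internally; the public API speaks µmol/kg and µatm.

pH is found by safeguarded bisection of the alkalinity residual on the
bracket [2, 12] (absolute tolerance 1e-9 in pH), fully vectorised over
numpy arrays so gridded fields solve in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

__all__ = [
    "SeawaterConditions",
    "EquilibriumConstants",
    "CarbonateSpeciation",
    "DomainError",
    "ConvergenceError",
    "equilibrium_constants",
    "reconstruct_alkalinity",
    "solve_carbonate_system",
    "dic_from_ta_pco2",
    "psi_factor",
    "revelle_factor",
    "schmidt_number",
    "gas_transfer_velocity",
]

# Molar masses (g/mol) used throughout the package.
M_C = 12.011
M_CACO3 = 100.0
M_N = 14.007
M_P = 30.974
M_FE = 55.845
M_CO2 = 44.009

PH_BRACKET = (2.0, 12.0)
PH_TOL = 1e-9
#: finite-difference step for psi and Revelle factor, µmol/kg
FD_STEP_UMOL = 1.0


class DomainError(ValueError):
    """An input is outside the physically/empirically valid domain."""


class ConvergenceError(RuntimeError):
    """The pH root is not bracketed or the solver failed to converge."""


@dataclass(frozen=True)
class SeawaterConditions:
    """Physico-chemical state of a seawater parcel.

    Parameters
    ----------
    salinity : float
        Practical salinity (dimensionless), 0 < S < 50.
    temperature : float
        In-situ temperature, °C, -2 < T < 40.
    pressure : float
        Hydrostatic pressure in dbar; only the surface (0) is supported.
    phosphate, silicate : float
        Total dissolved phosphate / silicate, µmol/kg (>= 0).
    """

    salinity: float = 35.0
    temperature: float = 25.0
    pressure: float = 0.0
    phosphate: float = 0.0
    silicate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.salinity < 50.0:
            raise DomainError(f"salinity {self.salinity} outside (0, 50)")
        if not -2.0 < self.temperature < 40.0:
            raise DomainError(f"temperature {self.temperature} outside (-2, 40)")
        if self.pressure < 0.0:
            raise DomainError(f"pressure {self.pressure} must be >= 0 dbar")
        if self.phosphate < 0.0:
            raise DomainError(f"phosphate {self.phosphate} must be >= 0")
        if self.silicate < 0.0:
            raise DomainError(f"silicate {self.silicate} must be >= 0")


@dataclass(frozen=True)
class EquilibriumConstants:
    """Stoichiometric equilibrium constants, total pH scale unless noted.

    ``ks`` and ``kf`` are kept on the free scale because they appear in the
    alkalinity balance through free-[H+] terms.  Totals (``total_boron`` etc.)
    are mol/kg-solution, salinity-scaled.
    """

    k0: float  # CO2 solubility, mol kg-1 atm-1 (Weiss 1974)
    k1: float  # H2CO3 -> HCO3-, total scale (Lueker 2000)
    k2: float  # HCO3- -> CO3--, total scale (Lueker 2000)
    kb: float  # boric acid, total scale (Dickson 1990b)
    kw: float  # water, converted SWS -> total (Millero 1995)
    ks: float  # bisulfate, free scale (Dickson 1990a)
    kf: float  # hydrogen fluoride, free scale (Perez & Fraga 1987)
    kp1: float  # phosphoric acid, SWS -> total (Millero 1995)
    kp2: float
    kp3: float
    ksi: float  # silicic acid, SWS -> total (Millero 1995)
    total_boron: float
    total_sulfate: float
    total_fluoride: float

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "k2", "kb", "kw", "ks", "kf",
                     "kp1", "kp2", "kp3", "ksi",
                     "total_boron", "total_sulfate", "total_fluoride"):
            if getattr(self, name) <= 0.0:
                raise DomainError(f"constant {name} must be strictly positive")
        if self.k1 <= self.k2:
            raise DomainError("K1 must exceed K2")


@dataclass(frozen=True)
class CarbonateSpeciation:
    """Solved CO2-system state (concentrations in µmol/kg, pCO2 in µatm)."""

    ph: float
    co2_aq: float
    hco3: float
    co3: float
    pco2: float
    dic: float
    ta: float
    r_ratio: float
    revelle_b: float
    psi: float
    conditions: SeawaterConditions = field(default=SeawaterConditions())


def _constants(s, t):
    """Constant set at salinity ``s`` and temperature ``t`` (°C).

    Array-capable core used by the gridded solvers; returns a plain
    namespace with the same attribute names as :class:`EquilibriumConstants`.
    """
    s = np.asarray(s, dtype=float)
    tk = np.asarray(t, dtype=float) + 273.15
    sqs = np.sqrt(s)
    lnt = np.log(tk)

    # Salinity-scaled totals (mol/kg-solution)
    tb = 0.000232 / 10.811 * s / 1.80655      # Uppstrom 1974 boron
    tso4 = 0.14 / 96.062 * s / 1.80655        # Morris & Riley 1966 sulfate
    tf = 0.000067 / 18.998 * s / 1.80655      # Riley 1965 fluoride

    # Weiss (1974) CO2 solubility, mol kg-1 atm-1
    t100 = tk / 100.0
    k0 = np.exp(-60.2409 + 93.4517 / t100 + 23.3585 * np.log(t100)
                + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100 ** 2))

    # Lueker et al. (2000) carbonic acid, total scale
    k1 = 10.0 ** -(3633.86 / tk - 61.2172 + 9.6777 * lnt
                   - 0.011555 * s + 0.0001152 * s ** 2)
    k2 = 10.0 ** -(471.78 / tk + 25.9290 - 3.16967 * lnt
                   - 0.01781 * s + 0.0001122 * s ** 2)

    # Dickson (1990b) boric acid, total scale
    kb = np.exp((-8966.90 - 2890.53 * sqs - 77.942 * s
                 + 1.728 * s ** 1.5 - 0.0996 * s ** 2) / tk
                + 148.0248 + 137.1942 * sqs + 1.62142 * s
                - (24.4344 + 25.085 * sqs + 0.2474 * s) * lnt
                + 0.053105 * sqs * tk)

    # Dickson (1990a) bisulfate, free scale, mol/kg-solution
    ion = 19.924 * s / (1000.0 - 1.005 * s)
    ks = np.exp(-4276.1 / tk + 141.328 - 23.093 * lnt
                + (-13856.0 / tk + 324.57 - 47.986 * lnt) * np.sqrt(ion)
                + (35474.0 / tk - 771.54 + 114.723 * lnt) * ion
                - 2698.0 / tk * ion ** 1.5 + 1776.0 / tk * ion ** 2
                + np.log(1.0 - 0.001005 * s))

    # Perez & Fraga (1987) HF, free scale
    kf = np.exp(874.0 / tk - 9.68 + 0.111 * sqs)

    sws_to_tot = (1.0 + tso4 / ks) / (1.0 + tso4 / ks + tf / kf)

    # Millero (1995) water, seawater scale -> total
    kw = np.exp(148.9802 - 13847.26 / tk - 23.6521 * lnt
                + (118.67 / tk - 5.977 + 1.0495 * lnt) * sqs
                - 0.01615 * s) * sws_to_tot

    # Millero (1995, from Yao & Millero) phosphoric acid, SWS -> total
    kp1 = np.exp(-4576.752 / tk + 115.525 - 18.453 * lnt
                 + (-106.736 / tk + 0.69171) * sqs
                 + (-0.65643 / tk - 0.01844) * s) * sws_to_tot
    kp2 = np.exp(-8814.715 / tk + 172.0883 - 27.927 * lnt
                 + (-160.340 / tk + 1.3566) * sqs
                 + (0.37335 / tk - 0.05778) * s) * sws_to_tot
    kp3 = np.exp(-3070.75 / tk - 18.141
                 + (17.27039 / tk + 2.81197) * sqs
                 + (-44.99486 / tk - 0.09984) * s) * sws_to_tot

    # Millero (1995) silicic acid (ionic-strength form), SWS -> total
    ksi = np.exp(-8904.2 / tk + 117.385 - 19.334 * lnt
                 + (-458.79 / tk + 3.5913) * np.sqrt(ion)
                 + (188.74 / tk - 1.5998) * ion
                 + (-12.1652 / tk + 0.07871) * ion ** 2
                 + np.log(1.0 - 0.001005 * s)) * sws_to_tot

    return SimpleNamespace(
        k0=k0, k1=k1, k2=k2, kb=kb, kw=kw, ks=ks, kf=kf,
        kp1=kp1, kp2=kp2, kp3=kp3, ksi=ksi,
        total_boron=tb, total_sulfate=tso4, total_fluoride=tf,
    )


def equilibrium_constants(cond: SeawaterConditions) -> EquilibriumConstants:
    """Evaluate the pinned constant set at the given S, T (surface pressure)."""
    k = _constants(cond.salinity, cond.temperature)
    return EquilibriumConstants(
        k0=float(k.k0), k1=float(k.k1), k2=float(k.k2), kb=float(k.kb),
        kw=float(k.kw), ks=float(k.ks), kf=float(k.kf), kp1=float(k.kp1),
        kp2=float(k.kp2), kp3=float(k.kp3), ksi=float(k.ksi),
        total_boron=float(k.total_boron),
        total_sulfate=float(k.total_sulfate),
        total_fluoride=float(k.total_fluoride),
    )


def _alkalinity(h: np.ndarray, dic: np.ndarray, k: EquilibriumConstants,
                tp: float, tsi: float) -> np.ndarray:
    """Model total alkalinity (mol/kg) at total-scale [H+] ``h``."""
    h_free = h / (1.0 + k.total_sulfate / k.ks)
    denom = h * h + k.k1 * h + k.k1 * k.k2
    ca = dic * (k.k1 * h + 2.0 * k.k1 * k.k2) / denom
    ba = k.total_boron * k.kb / (k.kb + h)
    oh = k.kw / h
    pd = (h ** 3 + k.kp1 * h ** 2 + k.kp1 * k.kp2 * h
          + k.kp1 * k.kp2 * k.kp3)
    phos = tp * (k.kp1 * k.kp2 * h + 2.0 * k.kp1 * k.kp2 * k.kp3
                 - h ** 3) / pd
    sioh = tsi * k.ksi / (k.ksi + h)
    hso4 = k.total_sulfate / (1.0 + k.ks / h_free)
    hf = k.total_fluoride / (1.0 + k.kf / h_free)
    return ca + ba + oh + phos + sioh - h_free - hso4 - hf


def _carbonate_alkalinity_from_co2(h, co2, k):
    return co2 * (k.k1 / h + 2.0 * k.k1 * k.k2 / (h * h))


def _bisect_ph(residual, lo: float = PH_BRACKET[0], hi: float = PH_BRACKET[1],
               tol: float = PH_TOL):
    """Vectorised safeguarded bisection of a pH-monotone residual.

    ``residual(ph_array)`` must be increasing in pH.  Raises
    :class:`ConvergenceError` (with the bracket-end residuals) where the
    root is not bracketed.
    """
    r_lo = residual(np.asarray(lo, dtype=float))
    r_hi = residual(np.asarray(hi, dtype=float))
    bad = (r_lo > 0.0) | (r_hi < 0.0)
    if np.any(bad):
        raise ConvergenceError(
            "alkalinity residual does not change sign on pH bracket "
            f"[{lo}, {hi}]: residual({lo}) = {np.atleast_1d(r_lo)[np.atleast_1d(bad)][:3]} "
            f"mol/kg, residual({hi}) = {np.atleast_1d(r_hi)[np.atleast_1d(bad)][:3]} mol/kg"
        )
    a = np.broadcast_to(np.asarray(lo, dtype=float), np.shape(r_lo)).copy()
    b = np.broadcast_to(np.asarray(hi, dtype=float), np.shape(r_hi)).copy()
    n_iter = int(np.ceil(np.log2((hi - lo) / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (a + b)
        pos = residual(mid) > 0.0
        b = np.where(pos, mid, b)
        a = np.where(pos, a, mid)
    return 0.5 * (a + b)


def _solve_ph(ta_mol, dic_mol, k: EquilibriumConstants,
              tp: float, tsi: float):
    ta_mol = np.asarray(ta_mol, dtype=float)
    dic_mol = np.asarray(dic_mol, dtype=float)

    def residual(ph):
        h = 10.0 ** (-np.asarray(ph, dtype=float))
        return _alkalinity(h, dic_mol, k, tp, tsi) - ta_mol

    return _bisect_ph(residual)


def _speciate(dic_mol, h, k: EquilibriumConstants):
    denom = h * h + k.k1 * h + k.k1 * k.k2
    co2 = dic_mol * h * h / denom
    hco3 = dic_mol * k.k1 * h / denom
    co3 = dic_mol * k.k1 * k.k2 / denom
    return co2, hco3, co3


def _co2_aq(ta_umol, dic_umol, k, cond) -> np.ndarray:
    """Dissolved CO2 (mol/kg) at TA, DIC given in µmol/kg."""
    ph = _solve_ph(np.asarray(ta_umol) * 1e-6, np.asarray(dic_umol) * 1e-6,
                   k, cond.phosphate * 1e-6, cond.silicate * 1e-6)
    co2, _, _ = _speciate(np.asarray(dic_umol) * 1e-6, 10.0 ** -ph, k)
    return co2


def _dic_eq(ta_umol, co2_mol, k: EquilibriumConstants,
            tp: float, tsi: float):
    """DIC (mol/kg) of water with alkalinity ``ta_umol`` holding dissolved
    CO2 fixed at ``co2_mol`` (i.e. equilibrated with an unchanged
    atmosphere)."""
    ta_arr = np.asarray(ta_umol, dtype=float) * 1e-6

    def residual(ph):
        h = 10.0 ** (-np.asarray(ph, dtype=float))
        ca = _carbonate_alkalinity_from_co2(h, co2_mol, k)
        other = _alkalinity(h, np.zeros_like(h), k, tp, tsi)
        return ca + other - ta_arr

    h = 10.0 ** -_bisect_ph(residual)
    return co2_mol * (1.0 + k.k1 / h + k.k1 * k.k2 / (h * h))


def _validate_ta_dic(ta: float, dic: float) -> None:
    if dic <= 0.0:
        raise DomainError(f"DIC {dic} µmol/kg must be strictly positive")
    if ta <= 0.0:
        raise DomainError(f"TA {ta} µmol/kg must be strictly positive")
    if dic >= ta + 500.0:
        raise DomainError(
            f"DIC {dic} µmol/kg implausibly exceeds TA {ta} + 500 µmol/kg")


def solve_carbonate_system(
    ta: float, dic: float, cond: SeawaterConditions = SeawaterConditions(),
) -> CarbonateSpeciation:
    """Solve the CO2 system from TA and DIC (both µmol/kg).

    Returns the full speciation together with the derived ratios
    (R = CO2*/DIC, Revelle factor, psi).  Scalar interface; gridded code
    uses the vectorised internals directly.
    """
    _validate_ta_dic(ta, dic)
    k = equilibrium_constants(cond)
    tp, tsi = cond.phosphate * 1e-6, cond.silicate * 1e-6

    ph = float(_solve_ph(ta * 1e-6, dic * 1e-6, k, tp, tsi))
    co2, hco3, co3 = _speciate(dic * 1e-6, 10.0 ** -ph, k)
    pco2 = co2 / k.k0 * 1e6  # µatm

    d = FD_STEP_UMOL
    # psi: precipitating delta mol CaCO3 takes DIC down by delta and TA by
    # 2*delta; the CO2 evaded once the parcel re-equilibrates with the
    # unchanged atmosphere is (dic - delta) minus the DIC the water holds at
    # the original pCO2 and the reduced TA.  In the delta->0 limit this is
    # 2*(dDIC/dTA)|pCO2 - 1, evaluated by central difference.
    dic_eq_hi = _dic_eq(ta + 2 * d, co2, k, tp, tsi)
    dic_eq_lo = _dic_eq(ta - 2 * d, co2, k, tp, tsi)
    psi = float(2.0 * (dic_eq_hi - dic_eq_lo) / (4.0 * d * 1e-6) - 1.0)

    # Revelle factor at constant TA
    co2_hi = _co2_aq(ta, dic + d, k, cond)
    co2_lo = _co2_aq(ta, dic - d, k, cond)
    revelle = float((co2_hi - co2_lo) / (2 * d * 1e-6) * (dic * 1e-6) / co2)

    return CarbonateSpeciation(
        ph=ph, co2_aq=float(co2) * 1e6, hco3=float(hco3) * 1e6,
        co3=float(co3) * 1e6, pco2=float(pco2), dic=float(dic), ta=float(ta),
        r_ratio=float(co2) * 1e6 / dic, revelle_b=revelle, psi=psi,
        conditions=cond,
    )


def dic_from_ta_pco2(
    ta, pco2, cond: SeawaterConditions = SeawaterConditions(),
):
    """Invert the system: DIC (µmol/kg) from TA (µmol/kg) and pCO2 (µatm).

    Vectorised: accepts scalars or broadcastable arrays.  Used to derive the
    DIC of seawater equilibrated with a prescribed atmosphere.
    """
    ta_arr = np.asarray(ta, dtype=float)
    pco2_arr = np.asarray(pco2, dtype=float)
    if np.any(ta_arr <= 0.0) or np.any(pco2_arr <= 0.0):
        raise DomainError("TA and pCO2 must be strictly positive")
    k = equilibrium_constants(cond)
    tp, tsi = cond.phosphate * 1e-6, cond.silicate * 1e-6
    co2 = k.k0 * pco2_arr * 1e-6  # mol/kg

    def residual(ph):
        h = 10.0 ** (-np.asarray(ph, dtype=float))
        ca = _carbonate_alkalinity_from_co2(h, co2, k)
        other = _alkalinity(h, np.zeros_like(h), k, tp, tsi)
        return ca + other - ta_arr * 1e-6

    ph = _bisect_ph(residual)
    h = 10.0 ** -ph
    dic = co2 * (1.0 + k.k1 / h + k.k1 * k.k2 / (h * h)) * 1e6
    if np.ndim(ta) == 0 and np.ndim(pco2) == 0:
        return float(dic)
    return dic


def reconstruct_alkalinity(spec: CarbonateSpeciation) -> float:
    """Recompute TA (µmol/kg) from a solved state's pH and DIC.

    Diagnostic for the solver round-trip: the result should match the input
    TA to well below 0.01 µmol/kg.
    """
    k = equilibrium_constants(spec.conditions)
    h = 10.0 ** -spec.ph
    return float(_alkalinity(h, spec.dic * 1e-6, k,
                             spec.conditions.phosphate * 1e-6,
                             spec.conditions.silicate * 1e-6)) * 1e6


def psi_factor(ta: float, dic: float,
               cond: SeawaterConditions = SeawaterConditions()) -> float:
    """Mol CO2 released per mol CaCO3 precipitated (Frankignoulle's psi).

    Precipitating δ mol CaCO3 removes δ from DIC and 2δ from TA; once the
    parcel re-equilibrates with an unchanged atmosphere the evaded CO2 per
    mol CaCO3 is 2·(∂DIC/∂TA at constant pCO2) − 1, evaluated by central
    finite difference with δ = 1 µmol/kg.  At present-day subtropical
    conditions psi ≈ 0.6 and it grows with pCO2 (the calcification-CO2
    positive feedback).
    """
    return solve_carbonate_system(ta, dic, cond).psi


def revelle_factor(ta: float, dic: float,
                   cond: SeawaterConditions = SeawaterConditions()) -> float:
    """Revelle buffer factor B = (∂pCO2/pCO2)/(∂DIC/DIC) at constant TA."""
    return solve_carbonate_system(ta, dic, cond).revelle_b


def schmidt_number(temperature):
    """Schmidt number of CO2 in seawater (Wanninkhof 2014 polynomial).

    Valid for -2 °C <= T <= 40 °C; normalised so Sc(20 °C) ≈ 668
    (the 660 reference value corresponds to freshwater-adjacent scaling).
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t < -2.0) or np.any(t > 40.0):
        raise DomainError(f"temperature {temperature} outside [-2, 40] °C")
    sc = (2116.8 - 136.25 * t + 4.7353 * t ** 2
          - 0.092307 * t ** 3 + 0.0007555 * t ** 4)
    if np.ndim(temperature) == 0:
        return float(sc)
    return sc


def gas_transfer_velocity(u10, temperature):
    """Gas transfer velocity G in m/s (quadratic wind-speed law).

    G = 0.251 · U10² · (Sc/660)^-0.5 in cm/h, divided by 360,000 to m/s.
    """
    u = np.asarray(u10, dtype=float)
    if np.any(u < 0.0):
        raise DomainError("wind speed u10 must be >= 0")
    sc = schmidt_number(temperature)
    g = 0.251 * u ** 2 * (np.asarray(sc) / 660.0) ** -0.5 / 360000.0
    if np.ndim(u10) == 0 and np.ndim(temperature) == 0:
        return float(g)
    return g
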