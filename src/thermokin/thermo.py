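"""Arrhenius activation energy and transition-state (Eyring) thermodynamics.

The activation energy Ea comes from the Arrhenius law k = A exp(-Ea/RT) via
ordinary least squares of ln(k) on 1/T; Ea = -slope * R. Ea is invariant to
the unit the rates are expressed in (a unit change shifts only the
intercept ln A).

The activation thermodynamics of inactivation at each temperature follow
transition-state theory with the rate expressed in s^-1:

    dH = Ea - R*T
    dG = -R*T * ln( k_s * h / (k_B * T) )
    dS = (dH - dG) / T

with k_B Boltzmann's constant, h Planck's constant and R the gas constant.
dG = dH - T*dS holds identically by construction, and dH falls by exactly
R*dT between temperatures.

``unit_mode='si'`` (default) converts min^-1 rates to s^-1 before the Eyring
step. ``unit_mode='paper-compat'`` inserts the min^-1 number into the Eyring
expression unconverted; this is unphysical but reproduces published apparent
dG/dS values for Weibull-derived (1/alpha) rates that were evidently
computed that way (the offset between the modes is exactly R*T*ln 60,
about 10.7 kJ mol^-1 at 40 degC).

Quantities derived from a Weibull rate surrogate (1/alpha) rather than a
true first-order rate constant are flagged ``apparent``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, InputError

__all__ = [
    "R_GAS",
    "BOLTZMANN",
    "PLANCK",
    "ArrheniusFit",
    "fit_arrhenius",
    "EyringPoint",
    "eyring_thermodynamics",
    "ThermoRecord",
    "ThermoSummary",
    "build_thermo_summary",
]

R_GAS = 8.314  # J mol^-1 K^-1
BOLTZMANN = 1.380649e-23  # J K^-1
PLANCK = 6.62607015e-34  # J s


@dataclass
class ArrheniusFit:
    ea_kj_mol: float
    intercept: float  # ln A, in the unit the rates were supplied in
    slope: float  # K
    r2: float


def fit_arrhenius(temperatures_K, rates) -> ArrheniusFit:
    """OLS of ln(rate) on 1/T (T in kelvin); Ea = -slope * R in kJ mol^-1.

    The rates may be in any single consistent unit; only the intercept
    depends on that unit.
    """
    t = np.asarray(temperatures_K, dtype=float)
    k = np.asarray(rates, dtype=float)
    if t.size != k.size:
        raise InputError("temperatures and rates must have equal length")
    if np.unique(t).size < 2:
        raise InputError("fit_arrhenius needs at least two distinct temperatures")
    if np.any(k <= 0):
        raise DomainError("fit_arrhenius requires strictly positive rates")
    if np.any(t <= 0):
        raise DomainError("temperatures must be positive kelvin")
    x, y = 1.0 / t, np.log(k)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ArrheniusFit(-slope * R_GAS / 1000.0, float(intercept), float(slope), r2)


@dataclass
class EyringPoint:
    dH: float  # kJ mol^-1
    dG: float  # kJ mol^-1
    dS: float  # J mol^-1 K^-1
    ratio: float  # T*dS/dH, dimensionless


def eyring_thermodynamics(
    k_per_min: float, T_K: float, ea_kj_mol: float, unit_mode: str = "si"
) -> EyringPoint:
    """Activation dH, dG, dS and the T*dS/dH ratio at one temperature.

    ``k_per_min`` is the inactivation rate (or 1/alpha surrogate) in min^-1.
    """
    if unit_mode not in ("si", "paper-compat"):
        raise InputError("unit_mode must be 'si' or 'paper-compat'")
    if not (k_per_min > 0.0):
        raise DomainError("eyring_thermodynamics requires k > 0")
    if not (T_K > 0.0):
        raise DomainError("eyring_thermodynamics requires T > 0 K")
    if not math.isfinite(ea_kj_mol):
        raise DomainError("Ea must be finite")
    k_s = k_per_min / 60.0 if unit_mode == "si" else k_per_min
    dH = ea_kj_mol * 1000.0 - R_GAS * T_K  # J mol^-1
    dG = -R_GAS * T_K * math.log(k_s * PLANCK / (BOLTZMANN * T_K))
    dS = (dH - dG) / T_K
    return EyringPoint(dH / 1000.0, dG / 1000.0, dS, T_K * dS / dH)


@dataclass
class ThermoRecord:
    temperature: float  # degC
    T_K: float
    dH: float  # kJ mol^-1
    dG: float  # kJ mol^-1
    dS: float  # J mol^-1 K^-1
    ratio: float  # T*dS/dH


@dataclass
class ThermoSummary:
    ea_kj_mol: float
    arrhenius_intercept: float
    arrhenius_r2: float
    arrhenius_rate_unit: str  # unit the rates carried into the Arrhenius fit
    records: list[ThermoRecord] = field(default_factory=list)
    apparent: bool = False  # True when derived from a Weibull 1/alpha surrogate
    unit_mode: str = "si"


def build_thermo_summary(
    temperatures_C,
    rates_per_min,
    *,
    arrhenius_rate_unit: str = "per_min",
    unit_mode: str = "si",
    apparent: bool = False,
) -> ThermoSummary:
    """Arrhenius fit plus per-temperature Eyring records.

    ``rates_per_min`` are always min^-1; ``arrhenius_rate_unit`` selects the
    unit in which they enter the Arrhenius regression ('per_min' or
    'per_h'), which changes only the reported intercept.
    """
    temps = np.asarray(temperatures_C, dtype=float)
    rates = np.asarray(rates_per_min, dtype=float)
    if arrhenius_rate_unit not in ("per_min", "per_h"):
        raise InputError("arrhenius_rate_unit must be 'per_min' or 'per_h'")
    arr_rates = rates * 60.0 if arrhenius_rate_unit == "per_h" else rates
    arr = fit_arrhenius(temps + 273.15, arr_rates)
    records = []
    for t_c, k in zip(temps, rates):
        pt = eyring_thermodynamics(k, t_c + 273.15, arr.ea_kj_mol, unit_mode)
        records.append(
            ThermoRecord(float(t_c), float(t_c + 273.15), pt.dH, pt.dG, pt.dS, pt.ratio)
        )
    return ThermoSummary(
        arr.ea_kj_mol, arr.intercept, arr.r2, arrhenius_rate_unit,
        records, apparent, unit_mode,
    )
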