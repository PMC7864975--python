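"""Air-water CO2 exchange: Henry's-law solubility, chemical enhancement,
and the daily areal carbon emission rate.

The areal CO2 flux follows the bulk gas-exchange model

    F = alpha * k * (C_water - C_eq)

where ``k`` is the gas transfer (piston) velocity in m d-1, ``C_water`` is
the dissolved CO2 concentration implied by the measured partial pressure,
``C_eq`` the concentration of water in equilibrium with the atmosphere, and
``alpha >= 1`` the pH-dependent chemical enhancement factor accounting for
the reacting carbonate system inside the diffusive boundary layer.
Concentrations come from Henry's law with the freshwater solubility
function of Weiss (1974); the enhancement factor uses the classical
stagnant-boundary-layer hydration model of Hoover & Berkshire (1969).

Diffusive CH4 evasion is folded in as a fixed share of total C emission
(default 1.19%), and a factor-1.5 seasonal adjustment converts a summer
pCO2 into an open-water-season effective value (spring pCO2 is taken as
twice the summer value and the two are averaged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import C_MOLAR_MASS, DomainError, InputError, PermafrostZone

__all__ = [
    "GasSample",
    "ExchangeParams",
    "co2_solubility",
    "dissolved_co2",
    "enhancement_factor",
    "co2_emission_rate",
    "add_ch4",
    "spring_adjust",
]

#: default atmospheric CO2 mixing ratio, ppm (~= uatm at 1 atm)
ATMOSPHERIC_PCO2_UATM = 390.0

#: Weiss (1974) freshwater CO2 solubility coefficients, mol L-1 atm-1
WEISS_A1 = -58.0931
WEISS_A2 = 90.5069
WEISS_A3 = 22.2940


@dataclass
class GasSample:
    """One transect observation of dissolved-gas state."""

    pCO2_water: float           # uatm
    water_temp: float           # degrees C
    pH: float
    pCO2_atm: float = ATMOSPHERIC_PCO2_UATM  # uatm
    pressure_kPa: float = 101.325
    zone: PermafrostZone | None = None
    latitude: float | None = None
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.pCO2_water < 0:
            raise InputError("pCO2_water must be non-negative")
        if not (0.0 < self.pH < 14.0):
            raise InputError("pH must lie in (0, 14)")


@dataclass
class ExchangeParams:
    """Constants of the gas-exchange model.

    ``k`` defaults to the regional median gas transfer coefficient measured
    by floating chamber on the largest rivers (4.464 m d-1); ``ch4_fraction``
    is the median share of CH4 in total C emission (0.0119 = 1.19%).
    """

    k: float = 4.464                     # m d-1
    ch4_fraction: float = 0.0119
    pCO2_atm: float = ATMOSPHERIC_PCO2_UATM
    enhancement_enabled: bool = True
    solubility_coefficients: tuple[float, float, float] = field(
        default=(WEISS_A1, WEISS_A2, WEISS_A3)
    )

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise DomainError("gas transfer coefficient k must be > 0")
        if not (0.0 <= self.ch4_fraction < 1.0):
            raise DomainError("ch4_fraction must lie in [0, 1)")


def co2_solubility(temp, coefficients=(WEISS_A1, WEISS_A2, WEISS_A3)):
    """Henry's-law CO2 solubility in fresh water, mol L-1 atm-1.

    Weiss (1974) fit at zero salinity; valid roughly -1..40 degrees C.
    Strictly decreasing in temperature (warm water holds less CO2).
    """
    temp = np.asarray(temp, dtype=float)
    if np.any(temp < -1.0) or np.any(temp > 40.0):
        raise DomainError("temperature outside the physical range [-1, 40] C")
    a1, a2, a3 = coefficients
    tk = temp + 273.15
    out = np.exp(a1 + a2 * (100.0 / tk) + a3 * np.log(tk / 100.0))
    return out if out.ndim else float(out)


def dissolved_co2(pCO2, temp, coefficients=(WEISS_A1, WEISS_A2, WEISS_A3)):
    """Dissolved CO2 concentration, mmol m-3, from partial pressure in uatm.

    C = K0(T) * pCO2 * 1e-6 (mol L-1), i.e. numerically K0 * pCO2 in
    mmol m-3 (1 mol L-1 = 1e6 mmol m-3).  The 1e-6 is the uatm->atm unit
    factor of the flux equation.
    """
    pCO2 = np.asarray(pCO2, dtype=float)
    if np.any(pCO2 < 0):
        raise DomainError("pCO2 must be non-negative")
    out = co2_solubility(temp, coefficients) * pCO2
    return out if np.ndim(out) else float(out)


# --- carbonate-system temperature functions (freshwater) ------------------
# First and second dissociation constants of carbonic acid: Harned & Davis
# (1943) and Harned & Scholes (1941); ion product of water: Harned & Owen.
# CO2 hydration rate: Johnson (1982).  OH- pathway rate anchored at
# 8500 M-1 s-1 (25 C) with an Arrhenius slope of ~52 kJ mol-1.


def _pK1(tk: np.ndarray) -> np.ndarray:
    return 3404.71 / tk + 0.032786 * tk - 14.8435


def _pK2(tk: np.ndarray) -> np.ndarray:
    return 2902.39 / tk + 0.02379 * tk - 6.4980


def _pKw(tk: np.ndarray) -> np.ndarray:
    return 4470.99 / tk + 0.017060 * tk - 6.0875


def _hydration_rate(tk: np.ndarray, oh: np.ndarray) -> np.ndarray:
    """Combined CO2 hydration rate r = k_CO2 + k_OH [OH-], s-1."""
    k_co2 = np.exp(1246.98 - 6.19e4 / tk - 183.0 * np.log(tk))
    k_oh = 8500.0 * np.exp(-6250.0 * (1.0 / tk - 1.0 / 298.15))
    return k_co2 + k_oh * oh


def _co2_diffusivity(tk: np.ndarray) -> np.ndarray:
    """CO2 diffusivity in water, m2 s-1 (Arrhenius, 1.92e-9 at 25 C)."""
    return 1.92e-9 * np.exp(-(19510.0 / 8.314) * (1.0 / tk - 1.0 / 298.15))


def enhancement_factor(pH, temp, k):
    """Chemical enhancement factor alpha >= 1 (Hoover & Berkshire 1969).

    alpha = tau / ((tau - 1) + tanh(Q)/Q) with Q = sqrt(r * tau * D) / k,
    where tau = CT/(CT - [CO2]) = 1 + [H+]^2/(K1[H+] + K1K2) measures how
    little of the inorganic pool is free CO2 (acidic water: tau -> inf and
    alpha -> 1; alkaline water: tau -> 1 and alpha -> Q/tanh(Q), large for
    slow exchange), r is the pH-dependent CO2 hydration rate and D the CO2
    diffusivity.  The flux calculation truncates pH at <8 upstream
    (observed river pH never exceeded 8); this operation enforces that
    contract.

    Parameters
    ----------
    pH : scalar or array, must be < 8
    temp : water temperature, degrees C
    k : gas transfer coefficient, m d-1
    """
    pH = np.asarray(pH, dtype=float)
    if np.any(pH >= 8.0):
        raise DomainError("pH must be truncated to < 8 before enhancement")
    if np.any(pH <= 0):
        raise DomainError("pH must be positive")
    if k <= 0:
        raise DomainError("k must be > 0")
    tk = np.asarray(temp, dtype=float) + 273.15
    h = 10.0 ** (-pH)
    oh = 10.0 ** (-(_pKw(tk))) / h
    K1 = 10.0 ** (-_pK1(tk))
    K2 = 10.0 ** (-_pK2(tk))
    tau = 1.0 + h**2 / (K1 * h + K1 * K2)
    r = _hydration_rate(tk, oh)
    D = _co2_diffusivity(tk)
    k_ms = k / 86400.0  # m d-1 -> m s-1
    Q = np.sqrt(r * tau * D) / k_ms
    alpha = tau / ((tau - 1.0) + np.tanh(Q) / Q)
    return alpha if alpha.ndim else float(alpha)


def co2_emission_rate(sample: GasSample, params: ExchangeParams | None = None):
    """Daily areal CO2 emission rate, g C m-2 d-1, for one gas sample.

    rate = alpha * k * (C(pCO2_water) - C(pCO2_atm)), converted to carbon
    mass with 12.011 g mol-1.  Sign follows the concentration gradient
    (negative = influx).
    """
    params = params or ExchangeParams()
    if sample.water_temp is None:
        raise InputError("water temperature required for solubility")
    coeffs = params.solubility_coefficients
    c_water = dissolved_co2(sample.pCO2_water, sample.water_temp, coeffs)
    c_atm = dissolved_co2(sample.pCO2_atm, sample.water_temp, coeffs)
    if params.enhancement_enabled:
        alpha = enhancement_factor(min(sample.pH, 7.999), sample.water_temp, params.k)
    else:
        alpha = 1.0
    # mmol m-3 -> mol m-3 (1e-3), times g C mol-1
    return alpha * params.k * (c_water - c_atm) * 1e-3 * C_MOLAR_MASS


def bulk_co2_rate(pCO2_water, pCO2_atm, temp, k, alpha=1.0):
    """Vectorised Eq.-style flux on arrays, g C m-2 d-1 (no CH4)."""
    dc = dissolved_co2(pCO2_water, temp) - dissolved_co2(pCO2_atm, temp)
    return np.asarray(alpha) * k * dc * 1e-3 * C_MOLAR_MASS


def add_ch4(co2_rate, ch4_fraction: float = 0.0119):
    """Total C (CO2 + diffusive CH4) rate given the CH4 share of the total.

    The fraction is a share of the *returned* total, so
    total = co2_rate / (1 - fraction); CH4 then constitutes exactly
    ``ch4_fraction`` of the output.
    """
    if not (0.0 <= ch4_fraction < 1.0):
        raise DomainError("ch4_fraction must lie in [0, 1)")
    return np.asarray(co2_rate) / (1.0 - ch4_fraction) if np.ndim(co2_rate) else (
        co2_rate / (1.0 - ch4_fraction)
    )


def spring_adjust(summer_pCO2):
    """Open-water-season effective pCO2 from a summer observation.

    Spring pCO2 is approximated as twice the summer value; the effective
    seasonal pCO2 is the average of the two, i.e. 1.5 x summer.
    """
    arr = np.asarray(summer_pCO2, dtype=float)
    if np.any(arr < 0):
        raise DomainError("pCO2 must be non-negative")
    out = 1.5 * arr
    return out if out.ndim else float(out)
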