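"""Physiological constants, temperature responses and unit conversions.

Everything downstream (the FvCB demand curve, the least-cost optimality
predictions and the scenario engine) works in partial pressures (Pa); CO2
mole fractions in ppm appear only at the user interface.  Temperature
responses of the Rubisco kinetic constants follow the Bernacchi-style
Arrhenius parameterisation that is standard in P-model implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "R_GAS",
    "TK25",
    "PATM_STD",
    "EnvironmentState",
    "PhotoConstants",
    "ValidationError",
    "arrhenius",
    "gamma_star",
    "michaelis_k",
    "viscosity_ratio",
    "ppm_to_pa",
    "pa_to_ppm",
]

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314
#: Reference temperature for all 25 degC constants, K.
TK25 = 298.15
#: Standard sea-level atmospheric pressure, Pa.
PATM_STD = 101325.0

#: Mole fraction of O2 in dry air (standard atmosphere).
O2_MOLE_FRACTION = 0.2095

TEMP_MIN_C = -30.0
TEMP_MAX_C = 60.0


class ValidationError(ValueError):
    """Raised when an environment or constant block violates its physical range."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class EnvironmentState:
    """Atmospheric forcing at one instant.

    Parameters
    ----------
    temp_c : float
        Air (= leaf) temperature, degC.  Leaf energy balance is not modelled.
    vpd : float
        Vapour pressure deficit of the air, Pa (strictly positive).
    ca_ppm : float
        Ambient CO2 mole fraction, µmol mol-1.
    ppfd : float
        Photosynthetic photon flux density, µmol m-2 s-1.
    patm : float
        Atmospheric pressure, Pa.
    """

    temp_c: float
    vpd: float
    ca_ppm: float
    ppfd: float = 800.0
    patm: float = PATM_STD

    def __post_init__(self) -> None:
        _require(TEMP_MIN_C <= self.temp_c <= TEMP_MAX_C,
                 f"temp_c={self.temp_c} outside validated range "
                 f"[{TEMP_MIN_C}, {TEMP_MAX_C}] degC")
        _require(self.vpd > 0, f"vpd must be > 0 Pa, got {self.vpd}")
        _require(self.ca_ppm > 0, f"ca_ppm must be > 0, got {self.ca_ppm}")
        _require(self.ppfd >= 0, f"ppfd must be >= 0, got {self.ppfd}")
        _require(self.patm > 0, f"patm must be > 0 Pa, got {self.patm}")

    @property
    def ca_pa(self) -> float:
        """Ambient CO2 partial pressure, Pa."""
        return ppm_to_pa(self.ca_ppm, self.patm)

    def replace(self, **changes) -> "EnvironmentState":
        return replace(self, **changes)


@dataclass(frozen=True)
class PhotoConstants:
    """Physiological constants with their temperature-response parameters.

    The 25 degC values and activation energies are the Bernacchi in-vivo
    estimates expressed at standard pressure; ``beta`` is the unit-cost
    ratio of carboxylation to transpiration capacity of least-cost theory;
    ``theta`` and ``c_jmax`` parameterise the curvature and marginal
    maintenance cost of the electron-transport capacity optimum;
    ``gamma_ratio`` is the conservative operational g_s : g_smax ratio.

    ``phi0`` is the intrinsic quantum yield of photosynthesis on a CO2
    basis (mol CO2 mol-1 photons); the default is calibrated once so that
    the reference temperate growth environment (25 degC, VPD 1 kPa,
    400 ppm, PPFD 800 µmol m-2 s-1, sea-level pressure) assimilates
    13.9 µmol CO2 m-2 s-1 at the fully coordinated optimum.
    """

    gamma_star25: float = 4.332          # Pa, CO2 compensation point at 25 degC
    kc25: float = 39.97                  # Pa, Michaelis constant of carboxylation
    ko25: float = 27480.0                # Pa, Michaelis constant of oxygenation
    dha_gamma_star: float = 37830.0      # J mol-1
    dha_kc: float = 79430.0              # J mol-1
    dha_ko: float = 36380.0              # J mol-1
    o2_mole_fraction: float = O2_MOLE_FRACTION
    beta: float = 146.0                  # unit-cost ratio b/a, dimensionless
    phi0: float = 0.034959               # mol CO2 mol-1 photons (see docstring)
    theta: float = 0.85                  # curvature of the J light response
    c_jmax: float = 0.05336251           # marginal maintenance cost of J_max
    gamma_ratio: float = 0.25            # long-term optimal g_s : g_smax
    jmax_method: str = "smith19"         # {"smith19", "wang17"} capacity optimum
    cstar_wang17: float = 0.41           # J_max cost used by the wang17 option
    rd_fraction: float = 0.0             # dark respiration as a fraction of V_cmax

    def __post_init__(self) -> None:
        for name in ("gamma_star25", "kc25", "ko25", "dha_gamma_star",
                     "dha_kc", "dha_ko", "o2_mole_fraction", "beta",
                     "phi0", "theta", "c_jmax", "gamma_ratio"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        _require(0 < self.gamma_ratio < 1, "gamma_ratio must lie in (0, 1)")
        _require(0 < self.phi0 < 0.125,
                 "phi0 must lie in (0, 0.125) mol CO2 per mol photons")
        _require(0 < self.theta < 1, "theta must lie in (0, 1)")
        _require(self.jmax_method in ("smith19", "wang17"),
                 f"unknown jmax_method {self.jmax_method!r}")
        _require(self.rd_fraction >= 0, "rd_fraction must be >= 0")

    def with_overrides(self, overrides: Mapping[str, float] | None) -> "PhotoConstants":
        """Return a copy with selected fields replaced (config override block)."""
        if not overrides:
            return self
        unknown = set(overrides) - set(self.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown constant override(s): {sorted(unknown)}")
        return replace(self, **dict(overrides))


def arrhenius(k25: float, dha: float, temp_c: float) -> float:
    """Arrhenius temperature scaling of a rate constant from its 25 degC value."""
    tk = temp_c + 273.15
    return k25 * math.exp(dha * (tk - TK25) / (TK25 * R_GAS * tk))


def gamma_star(temp_c: float, patm: float = PATM_STD,
               constants: PhotoConstants | None = None) -> float:
    """Photorespiratory CO2 compensation point Γ*, Pa.

    Scales the 25 degC reference with the Arrhenius response and linearly
    with pressure (Γ* is proportional to the O2 partial pressure).
    """
    c = constants or PhotoConstants()
    _require(TEMP_MIN_C <= temp_c <= TEMP_MAX_C,
             f"temp_c={temp_c} outside validated range")
    return arrhenius(c.gamma_star25 * patm / PATM_STD, c.dha_gamma_star, temp_c)


def michaelis_k(temp_c: float, patm: float = PATM_STD,
                constants: PhotoConstants | None = None) -> float:
    """Effective Michaelis-Menten coefficient K = Kc (1 + pO2/Ko), Pa."""
    c = constants or PhotoConstants()
    _require(TEMP_MIN_C <= temp_c <= TEMP_MAX_C,
             f"temp_c={temp_c} outside validated range")
    kc = arrhenius(c.kc25 * patm / PATM_STD, c.dha_kc, temp_c)
    ko = arrhenius(c.ko25 * patm / PATM_STD, c.dha_ko, temp_c)
    po2 = c.o2_mole_fraction * patm
    return kc * (1.0 + po2 / ko)


def viscosity_ratio(temp_c: float) -> float:
    """Viscosity of liquid water relative to 25 degC (η*), dimensionless.

    Uses the Vogel-Fulcher-Tammann closed form η(T) = A·10^(B/(T−C)) with
    the standard coefficients for water (B = 247.8 K, C = 140 K); the
    prefactor cancels in the ratio.  Valid for liquid water, 0-100 degC.
    """
    _require(0.0 < temp_c < 100.0,
             f"viscosity ratio defined for liquid water (0-100 degC), got {temp_c}")

    def log10_eta(tc: float) -> float:
        return 247.8 / (tc + 273.15 - 140.0)

    return 10.0 ** (log10_eta(temp_c) - log10_eta(25.0))


def ppm_to_pa(ca_ppm: float, patm: float = PATM_STD) -> float:
    """Convert a CO2 mole fraction (µmol mol-1) to partial pressure (Pa)."""
    _require(ca_ppm >= 0, "ca_ppm must be non-negative")
    _require(patm > 0, "patm must be positive")
    return ca_ppm * 1e-6 * patm


def pa_to_ppm(ca_pa: float, patm: float = PATM_STD) -> float:
    """Convert a CO2 partial pressure (Pa) to mole fraction (µmol mol-1)."""
    _require(patm > 0, "patm must be positive")
    return ca_pa / patm * 1e6
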