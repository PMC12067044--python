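"""Temperature-dependent physical properties of water-based fermentation broth.

Gas solubilities follow Henry's law with a van't Hoff temperature correction,

    K_H(T) = K_H(T_ref) * exp(B * (1/T - 1/T_ref)),

with reference solubilities in pure water at 298.15 K and B the solubility
enthalpy parameter (K).  The defaults are compilation values (Sander-type
ln K vs 1/T form); every constant is overridable through the configuration
file so a different compilation can be swapped in without code changes.

Water vapor pressure uses an Antoine correlation fitted to steam-table data
over 273-373 K:  log10(p/bar) = A - B/(T - C).

Dissolved CO2 is treated as molecular CO2 only; at the operating pH of 6
carbonate speciation is negligible and is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import DomainError, UnknownGasError

SUPPORTED_GASES = ("O2", "CO2", "N2", "H2", "CH4", "CO")

#: Solubility in pure water at 298.15 K, mol/(kg bar).
HENRY_REF_DEFAULT: Mapping[str, float] = {
    "O2": 1.2e-3,
    "CO2": 3.3e-2,
    "N2": 6.4e-4,
    "H2": 7.8e-4,
    "CH4": 1.57e-3,
    "CO": 9.7e-4,
}

#: van't Hoff solubility-enthalpy parameter, K.
HENRY_VANT_HOFF_DEFAULT: Mapping[str, float] = {
    "O2": 1500.0,
    "CO2": 2400.0,
    "N2": 1600.0,
    "H2": 530.0,
    "CH4": 1900.0,
    "CO": 1300.0,
}

#: Liquid-film diffusivities in water, m^2/s (25 C literature values; only the
#: CO2/O2 ratio enters the model, through the transfer-coefficient correction).
DIFFUSIVITY_DEFAULT: Mapping[str, float] = {
    "O2": 2.10e-9,
    "CO2": 1.92e-9,
}


@dataclass(frozen=True)
class PhysicalProperties:
    """Physical-property set used by all other modules.

    Parameters
    ----------
    henry_ref : mapping gas -> mol/(kg bar) at ``T_ref``.
    henry_vant_hoff : mapping gas -> van't Hoff parameter, K.
    diffusivity : mapping gas -> liquid-film diffusivity, m^2/s.
    diffusivity_ratio_CO2_O2 : direct override of D_CO2/D_O2; ``None`` means
        compute it from ``diffusivity``.
    rho_L : ungassed liquid density, kg/m^3.
    cp : liquid heat capacity, kJ/(kg K).
    dH_evap : molar latent heat of water, kJ/mol.
    heat_per_O2 : heat released per mole O2 consumed, kJ/mol.
    U : overall heat-transfer coefficient of the cooling exchangers, kW/(m^2 K).
    antoine : (A, B, C) with log10(p_sat/bar) = A - B/(T/K - C).
    """

    henry_ref: Mapping[str, float] = field(
        default_factory=lambda: dict(HENRY_REF_DEFAULT))
    henry_vant_hoff: Mapping[str, float] = field(
        default_factory=lambda: dict(HENRY_VANT_HOFF_DEFAULT))
    diffusivity: Mapping[str, float] = field(
        default_factory=lambda: dict(DIFFUSIVITY_DEFAULT))
    diffusivity_ratio_CO2_O2: float | None = None
    rho_L: float = 1000.0
    cp: float = 4.18
    dH_evap: float = 43.5
    heat_per_O2: float = 460.0
    U: float = 1.4
    antoine: tuple[float, float, float] = (5.11564, 1687.537, 42.98)
    T_ref: float = 298.15

    def __post_init__(self) -> None:
        for name, val in (("rho_L", self.rho_L), ("cp", self.cp),
                          ("dH_evap", self.dH_evap), ("U", self.U),
                          ("heat_per_O2", self.heat_per_O2)):
            if val <= 0:
                raise DomainError(f"{name} must be strictly positive, got {val}")
        for gas, val in self.henry_ref.items():
            if val <= 0:
                raise DomainError(f"henry_ref[{gas}] must be positive, got {val}")
        for gas, val in self.diffusivity.items():
            if val <= 0:
                raise DomainError(f"diffusivity[{gas}] must be positive, got {val}")

    def co2_o2_diffusivity_ratio(self) -> float:
        """D_CO2/D_O2, either the direct override or the diffusivity quotient."""
        if self.diffusivity_ratio_CO2_O2 is not None:
            return self.diffusivity_ratio_CO2_O2
        return self.diffusivity["CO2"] / self.diffusivity["O2"]


DEFAULT_PROPERTIES = PhysicalProperties()


def _check_temperature(T: float) -> None:
    if not 273.0 < T < 373.16:
        raise DomainError(
            f"temperature {T} K outside the liquid-water range (273, 373) K")


def henry_coefficient(gas: str, T: float,
                      props: PhysicalProperties = DEFAULT_PROPERTIES) -> float:
    """Solubility coefficient of ``gas`` in water at temperature ``T``.

    Parameters
    ----------
    gas : one of O2, CO2, N2, H2, CH4, CO.
    T : temperature, K (273-373).

    Returns
    -------
    float
        Henry solubility, mol/(kg bar): the equilibrium dissolved
        concentration per bar of partial pressure.
    """
    if gas not in props.henry_ref:
        raise UnknownGasError(
            f"unsupported gas {gas!r}; supported: {sorted(props.henry_ref)}")
    _check_temperature(T)
    ref = props.henry_ref[gas]
    b = props.henry_vant_hoff[gas]
    return ref * math.exp(b * (1.0 / T - 1.0 / props.T_ref))


def water_vapor_pressure(T: float,
                         props: PhysicalProperties = DEFAULT_PROPERTIES) -> float:
    """Saturated vapor pressure of water at ``T`` (K), in bar."""
    _check_temperature(T)
    a, b, c = props.antoine
    return 10.0 ** (a - b / (T - c))
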