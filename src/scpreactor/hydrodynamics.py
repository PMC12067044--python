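"""Bubble-column hydrodynamics and gas-liquid transfer.

Correlations for a coalescing broth in the heterogeneous (churn-turbulent)
flow regime:

    kLa_O2 [1/s] = 0.32 * vsG_mean^0.7 * 1.022^(T_C - 20)
    eps_G        = 0.6  * vsG_mean^0.7

with the mean superficial velocity the logarithmic mean of the top and
bottom values.  The correlations were fitted for vsG_mean in 0.04-0.30 m/s;
outside that window a warning is logged but the value is still returned.
The CO2 transfer coefficient is the O2 value scaled by sqrt(D_CO2/D_O2).

The equilibrium (driving-force) concentration uses the well-mixed off-gas
composition and, by default, the logarithmic mean of the top and bottom
total pressures; arithmetic-mean and top-pressure variants are selectable
for sensitivity studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import DomainError, SaturationError
from .properties import (DEFAULT_PROPERTIES, PhysicalProperties,
                         henry_coefficient, water_vapor_pressure)

R_GAS = 8.314462618       # J/(mol K)
G_ACCEL = 9.80665         # m/s^2


@dataclass(frozen=True)
class ReactorGeometry:
    """Cylindrical bubble-column vessel.

    The diameter follows from the volume and aspect ratio,
    D_R = (4 V_R / (aspect_ratio pi))^(1/3); the aerated broth occupies
    ``fill_fraction`` of the vessel volume (headspace above it).
    """

    V_R: float = 600.0          # m^3
    aspect_ratio: float = 6.0   # H_R/D_R
    fill_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.V_R <= 0 or self.aspect_ratio <= 0:
            raise DomainError("vessel volume and aspect ratio must be positive")
        if not 0.0 < self.fill_fraction <= 1.0:
            raise DomainError(
                f"fill_fraction must be in (0, 1], got {self.fill_fraction}")

    @property
    def D_R(self) -> float:
        return (4.0 * self.V_R / (self.aspect_ratio * math.pi)) ** (1.0 / 3.0)

    @property
    def H_R(self) -> float:
        return self.aspect_ratio * self.D_R

    @property
    def cross_section(self) -> float:
        return math.pi / 4.0 * self.D_R ** 2

    @property
    def V_aerated(self) -> float:
        return self.fill_fraction * self.V_R

    @property
    def H_aerated(self) -> float:
        return self.fill_fraction * self.H_R


@dataclass(frozen=True)
class CorrelationSet:
    """Constants of the kLa / hold-up correlations, all overridable.

    ``coalescence_factor`` multiplies kLa (1 = coalescing broth baseline);
    ``pressure_average`` selects how the driving-force pressure is averaged
    over the column: ``"log_mean"`` (default), ``"arith_mean"`` or ``"top"``.
    """

    kla_coefficient: float = 0.32
    kla_exponent: float = 0.7
    kla_temperature_base: float = 1.022
    kla_reference_T_C: float = 20.0
    holdup_coefficient: float = 0.6
    holdup_exponent: float = 0.7
    coalescence_factor: float = 1.0
    pressure_average: str = "log_mean"
    velocity_window: tuple[float, float] = (0.04, 0.30)


DEFAULT_CORRELATIONS = CorrelationSet()


@dataclass
class GasColumnState:
    """Gas-side state of a converged column."""

    FG_N_in: float        # mol/h
    FG_N_out: float       # mol/h
    y_O2: float           # off-gas mole fractions (well-mixed gas phase)
    y_CO2: float
    y_N2: float
    y_W: float
    p_top: float          # bar
    p_bot: float          # bar
    vsG_top: float        # m/s
    vsG_bot: float        # m/s
    vsG_mean: float       # m/s
    eps_G: float          # gas hold-up, -

    def mole_fraction_sum(self) -> float:
        return self.y_O2 + self.y_CO2 + self.y_N2 + self.y_W


def _warn_window(vsG_mean: float, corr: CorrelationSet) -> None:
    lo, hi = corr.velocity_window
    if not lo * (1 - 1e-9) <= vsG_mean <= hi * (1 + 1e-9):
        warnings.warn(
            f"vsG_mean = {vsG_mean:.3g} m/s outside correlation validity "
            f"window [{lo}, {hi}] m/s (heterogeneous regime)",
            stacklevel=3)


def kla(vsG_mean: float, T_C: float, gas: str = "O2",
        props: PhysicalProperties = DEFAULT_PROPERTIES,
        corr: CorrelationSet = DEFAULT_CORRELATIONS, *,
        warn: bool = True) -> float:
    """Volumetric transfer coefficient, 1/h.

    For O2 the coalescing-broth correlation is evaluated directly; for CO2
    the O2 value is scaled by sqrt(D_CO2/D_O2).
    """
    if vsG_mean <= 0:
        raise DomainError(f"vsG_mean must be positive, got {vsG_mean}")
    if warn:
        _warn_window(vsG_mean, corr)
    base = (corr.kla_coefficient * vsG_mean ** corr.kla_exponent
            * corr.kla_temperature_base ** (T_C - corr.kla_reference_T_C))
    value = base * corr.coalescence_factor * 3600.0
    if gas == "O2":
        return value
    if gas == "CO2":
        return value * math.sqrt(props.co2_o2_diffusivity_ratio())
    raise DomainError(f"kla correlation defined for O2 and CO2 only, got {gas!r}")


def gas_holdup(vsG_mean: float,
               corr: CorrelationSet = DEFAULT_CORRELATIONS) -> float:
    """Gas hold-up (volume fraction of bubbles in the aerated broth)."""
    if vsG_mean < 0:
        raise DomainError(f"vsG_mean must be non-negative, got {vsG_mean}")
    return min(corr.holdup_coefficient * vsG_mean ** corr.holdup_exponent, 0.99)


def superficial_velocity(FG_N: float, p: float, T: float,
                         geometry: ReactorGeometry) -> float:
    """Ideal-gas superficial velocity, m/s, from a molar flow in mol/h."""
    if p <= 0:
        raise DomainError(f"pressure must be positive, got {p} bar")
    if FG_N < 0 or T <= 0:
        raise DomainError("molar flow must be >= 0 and temperature > 0")
    return (FG_N / 3600.0) * R_GAS * T / (p * 1e5) / geometry.cross_section


def molar_flow(vsG: float, p: float, T: float,
               geometry: ReactorGeometry) -> float:
    """Exact algebraic inverse of :func:`superficial_velocity`, mol/h."""
    if p <= 0:
        raise DomainError(f"pressure must be positive, got {p} bar")
    return vsG * (p * 1e5) * geometry.cross_section / (R_GAS * T) * 3600.0


def log_mean(a: float, b: float) -> float:
    """Logarithmic mean (a - b)/ln(a/b), continuous at a = b."""
    if a <= 0 or b <= 0:
        raise DomainError(f"log mean requires positive inputs, got {a}, {b}")
    if abs(a - b) <= 1e-12 * max(a, b):
        return 0.5 * (a + b)
    return (a - b) / math.log(a / b)


def bottom_pressure(p_top: float, eps_G: float, geometry: ReactorGeometry,
                    rho_L: float = 1000.0) -> float:
    """Top pressure plus the hydrostatic head of the aerated liquid, bar."""
    if not 0.0 <= eps_G < 1.0:
        raise DomainError(f"gas hold-up must be in [0, 1), got {eps_G}")
    head = rho_L * (1.0 - eps_G) * G_ACCEL * geometry.H_aerated / 1e5
    return p_top + head


def effective_pressure(p_top: float, p_bot: float,
                       corr: CorrelationSet = DEFAULT_CORRELATIONS) -> float:
    """Column-average total pressure entering the equilibrium concentration."""
    mode = corr.pressure_average
    if mode == "log_mean":
        return log_mean(p_bot, p_top)
    if mode == "arith_mean":
        return 0.5 * (p_bot + p_top)
    if mode == "top":
        return p_top
    raise DomainError(f"unknown pressure_average mode {mode!r}")


def transfer_rate(gas: str, y_out: float, p_eff: float, C_bulk: float,
                  kla_val: float, T: float,
                  props: PhysicalProperties = DEFAULT_PROPERTIES) -> float:
    """Gas-to-liquid transfer rate N = kLa (K_H y p - C_bulk), mol/(kg_L h).

    Positive means net transfer into the liquid; a negative value is legal
    (CO2 strips from the liquid into the bubbles).
    """
    if not 0.0 <= y_out <= 1.0:
        raise DomainError(f"mole fraction must be in [0, 1], got {y_out}")
    if kla_val <= 0:
        raise DomainError(f"kLa must be positive, got {kla_val}")
    c_eq = henry_coefficient(gas, T, props) * y_out * p_eff
    return kla_val * (c_eq - C_bulk)


def evaporation_rate(FG_N_out: float, p_top: float, T: float, M_L: float,
                     props: PhysicalProperties = DEFAULT_PROPERTIES,
                     ) -> tuple[float, float]:
    """Water evaporation into the off-gas, assuming vapor-liquid equilibrium.

    Returns ``(N_W, y_W)`` with ``N_W`` the (negative) water transfer rate in
    mol/(kg_L h) and ``y_W = p_sat/p_top`` the off-gas water fraction.
    """
    if FG_N_out <= 0 or M_L <= 0:
        raise DomainError("gas outflow and liquid mass must be positive")
    p_sat = water_vapor_pressure(T, props)
    if p_sat >= p_top:
        raise SaturationError(
            f"p_sat = {p_sat:.3g} bar >= total pressure {p_top:.3g} bar: "
            "gas cannot carry the equilibrium water fraction")
    y_W = p_sat / p_top
    return -y_W * FG_N_out / M_L, y_W
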