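"""Heat balance, external cooling-loop sizing and cell-stress assessment.

The steady-state heat balance is

    0 = Q_r - Q_evap - Q_cool

with the heat of reaction proportional to the O2 consumption (460 kJ per
mole of O2 by default) and the evaporative term set by the off-gas water
flow and the latent heat of water.  The cooling duty is removed in an
external loop of parallel shell-and-tube exchangers sized from
Q = U A dT_lm; the loop broth flow follows from the allowed broth
temperature drop.  An internal helical coil cannot provide the required
area at the base case, which this module quantifies.

The stress profile estimates what cells experience per pass through the
loop: tube wall shear, pump-clearance shear, the residence time in the
exchanger path, and the times in which the dissolved O2 and substrate
reservoirs would be depleted at the bulk reaction rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateDesignError, DomainError
from .hydrodynamics import ReactorGeometry
from .properties import DEFAULT_PROPERTIES, PhysicalProperties
from .steady_state import SteadyStateSolution


@dataclass(frozen=True)
class CoolingParameters:
    """Exchanger catalogue and loop assumptions (all overridable)."""

    dT_lm: float = 15.0                 # log-mean temperature difference, K
    dT_loop: float = 15.0               # broth drop across the loop, K
    unit_area_max: float = 430.0        # largest catalogue exchanger, m^2
    unit_area_design: float = 400.0     # design area per installed unit, m^2
    tubes_per_unit: int = 1269          # at the catalogue maximum area
    tube_id: float = 0.019              # m
    tube_length: float = 6.1            # m
    scale_tubes_to_design_area: bool = True
    viscosity: float = 0.010            # broth viscosity, Pa s
    wall_shear_model: str = "simple"    # "simple": mu*v/d; "laminar": 8*mu*v/d
    extra_piping: float = 10.0          # m of connecting piping
    pump_rpm: tuple[float, float] = (60.0, 600.0)
    impeller_diameter: float = 0.6      # m
    clearance: float = 3.0e-4           # blade-tip/casing clearance, m


DEFAULT_COOLING = CoolingParameters()


@dataclass
class HeatBalance:
    Q_r: float                  # kW
    Q_evap: float               # kW
    Q_cool: float               # kW
    specific_load: float        # W per kg of liquid


@dataclass
class CoolingDesign:
    heat: HeatBalance
    A_cool: float               # required exchanger area, m^2
    n_exchangers: int
    tubes_per_exchanger: float  # effective count (scaled to design area)
    F_cool: float               # loop broth flow, kg/s
    passes_per_hour: float
    tube_velocity: float        # m/s, single tube pass
    coil_area_available: float  # m^2, internal helical coil alternative
    dT_lm: float
    dT_loop: float


@dataclass
class StressProfile:
    tube_velocity: float        # m/s at the chosen number of tube passes
    wall_shear_tube: float      # Pa
    pump_shear_range: tuple[float, float]  # Pa over the rpm range
    t_O2_depletion: float       # s
    t_S_depletion: float        # s
    t_loop_residence: float     # s
    viscosity: float            # Pa s


def heat_balance(sol: SteadyStateSolution,
                 props: PhysicalProperties = DEFAULT_PROPERTIES) -> HeatBalance:
    """Reaction, evaporation and cooling heat rates (kW) of a solution."""
    consumed_O2 = -sol.R_O2_mol_h  # mol/h
    Q_r = props.heat_per_O2 * consumed_O2 / 3600.0
    Q_evap = sol.gas.FG_N_out * sol.gas.y_W * props.dH_evap / 3600.0
    Q_cool = Q_r - Q_evap
    if Q_cool < 0:
        raise DomainError("evaporation exceeds the heat of reaction")
    specific = props.heat_per_O2 * sol.N_O2 / 3.6  # kJ/mol * mol/(kg h) -> W/kg
    return HeatBalance(Q_r=Q_r, Q_evap=Q_evap, Q_cool=Q_cool,
                       specific_load=specific)


def coil_area(geometry: ReactorGeometry) -> float:
    """Heat-transfer area of an internal helical coil, m^2.

    Rules: pipe diameter D_R/30, pitch twice the pipe diameter, number of
    turns equal to the aerated-liquid height over (diameter + pitch), helix
    diameter equal to the vessel diameter.
    """
    d = geometry.D_R / 30.0
    pitch = 2.0 * d
    turns = geometry.H_aerated / (d + pitch)
    return turns * math.pi * d * math.pi * geometry.D_R


def size_cooling_system(heat: HeatBalance, M_L: float,
                        props: PhysicalProperties = DEFAULT_PROPERTIES,
                        geometry: ReactorGeometry = ReactorGeometry(),
                        params: CoolingParameters = DEFAULT_COOLING,
                        ) -> CoolingDesign:
    """Size the external loop for a given heat balance and liquid mass."""
    if heat.Q_cool < 0:
        raise DomainError("cooling duty must be non-negative")
    A_cool = heat.Q_cool / (props.U * params.dT_lm)
    # unit count from the catalogue maximum area; units are then installed
    # at the (smaller) design area each
    n = math.ceil(A_cool / params.unit_area_max) if A_cool > 0 else 0
    if params.scale_tubes_to_design_area:
        tubes = params.tubes_per_unit * params.unit_area_design / params.unit_area_max
    else:
        tubes = float(params.tubes_per_unit)
    F_cool = heat.Q_cool / (props.cp * params.dT_loop)  # kg/s
    passes = F_cool * 3600.0 / M_L if M_L > 0 else 0.0
    tube_xs = math.pi / 4.0 * params.tube_id ** 2
    if n > 0 and F_cool > 0:
        v_tube = F_cool / props.rho_L / (n * tubes * tube_xs)
    else:
        v_tube = 0.0
    return CoolingDesign(heat=heat, A_cool=A_cool, n_exchangers=n,
                         tubes_per_exchanger=tubes, F_cool=F_cool,
                         passes_per_hour=passes, tube_velocity=v_tube,
                         coil_area_available=coil_area(geometry),
                         dT_lm=params.dT_lm, dT_loop=params.dT_loop)


def wall_shear(velocity: float, params: CoolingParameters = DEFAULT_COOLING,
               ) -> float:
    """Tube wall shear stress, Pa, at a given flow velocity.

    The default estimator is mu*v/d; the rigorous laminar wall value
    8*mu*v/d is available through ``wall_shear_model = "laminar"``.
    """
    factor = {"simple": 1.0, "laminar": 8.0}
    if params.wall_shear_model not in factor:
        raise DomainError(
            f"unknown wall_shear_model {params.wall_shear_model!r}")
    return (factor[params.wall_shear_model] * params.viscosity * velocity
            / params.tube_id)


def pump_shear(rpm: float, params: CoolingParameters = DEFAULT_COOLING) -> float:
    """Shear stress in the pump blade-tip clearance, Pa."""
    tip_speed = math.pi * params.impeller_diameter * rpm / 60.0
    return params.viscosity * tip_speed / params.clearance


def stress_profile(design: CoolingDesign, sol: SteadyStateSolution,
                   passes_in_tubes: int = 1,
                   params: CoolingParameters = DEFAULT_COOLING,
                   ) -> StressProfile:
    """Cell-stress indicators for one transit through the cooling loop.

    ``passes_in_tubes`` splits the tube bundle into serial passes, raising
    the velocity proportionally; the flow path is the tube length times the
    number of passes plus the connecting piping.
    """
    v = design.tube_velocity * passes_in_tubes
    if v <= 0:
        raise DegenerateDesignError("zero tube velocity: nothing flows")
    path = params.tube_length * passes_in_tubes + params.extra_piping
    residence = path / v

    # zero-order depletion of the dissolved reservoirs at the bulk rates
    r_O2 = -sol.R_O2_mol_h / sol.M_L      # mol/(kg h), consumption positive
    r_S = -sol.R_S_mol_h / sol.M_L
    if r_O2 <= 0 or r_S <= 0:
        raise DegenerateDesignError("non-positive consumption rate")
    t_O2 = sol.op.C_O2_set / r_O2 * 3600.0
    t_S = sol.C_S / r_S * 3600.0

    return StressProfile(
        tube_velocity=v,
        wall_shear_tube=wall_shear(v, params),
        pump_shear_range=(pump_shear(params.pump_rpm[0], params),
                          pump_shear(params.pump_rpm[1], params)),
        t_O2_depletion=t_O2, t_S_depletion=t_S,
        t_loop_residence=residence,
        viscosity=params.viscosity)
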