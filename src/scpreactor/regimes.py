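"""Characteristic-time regime analysis for scale-up diagnosis.

Each mechanism gets a reservoir-over-rate time constant; when the mixing
time exceeds a mechanism's time constant by more than an order of
magnitude, spatial gradients of that quantity are expected in the column.

Liquid mixing is driven by the gas-induced internal circulation flow

    F_mix,L = 0.3 * D_R^(5/3) * (F_G,mean^V)^(1/3) * g^(1/3)   [m^3/s]

and the liquid mixing time is taken as a fixed number of circulation times
(default 4, the usual rule for tall vessels).  The gas-phase mixing time is
the flow-through time divided by a back-mixing speed-up factor (default 3);
no established correlation exists for gas back-mixing in this regime, so
both multipliers are exposed as strategy parameters rather than buried
constants, and only ratio-level conclusions should be drawn from them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DegenerateDesignError, DomainError
from .hydrodynamics import G_ACCEL, ReactorGeometry
from .properties import DEFAULT_PROPERTIES, PhysicalProperties, henry_coefficient
from .steady_state import SteadyStateSolution


@dataclass(frozen=True)
class TimeStrategies:
    """Tunable definitions behind the characteristic times."""

    mix_circulations: float = 4.0     # liquid mixing time / circulation time
    gas_mixing_speedup: float = 3.0   # flow-through time / gas mixing time
    dT_allowed: float = 1.0           # tolerated temperature excursion, K


DEFAULT_STRATEGIES = TimeStrategies()


@dataclass
class CharacteristicTimes:
    tau_mix_L: float   # liquid mixing, s
    tau_mix_G: float   # gas mixing, s
    tau_FG: float      # gas flow-through, s
    tau_S: float       # substrate consumption, s
    tau_O2: float      # dissolved-O2 consumption, s
    tau_CO2: float     # dissolved-CO2 production, s
    tau_heat: float    # heat accumulation to dT_allowed, s


@dataclass
class GradientFlag:
    mechanism: str
    reference: str
    ratio: float


def mixing_flow(geometry: ReactorGeometry, FG_volumetric_mean: float) -> float:
    """Gas-driven internal liquid circulation flow, m^3/s."""
    if FG_volumetric_mean < 0:
        raise DomainError("volumetric gas flow must be non-negative")
    return (0.3 * geometry.D_R ** (5.0 / 3.0)
            * FG_volumetric_mean ** (1.0 / 3.0) * G_ACCEL ** (1.0 / 3.0))


def characteristic_times(sol: SteadyStateSolution,
                         geometry: ReactorGeometry = ReactorGeometry(),
                         props: PhysicalProperties = DEFAULT_PROPERTIES,
                         strategies: TimeStrategies = DEFAULT_STRATEGIES,
                         ) -> CharacteristicTimes:
    """Compute all time constants for a converged operating point."""
    Q_gas = sol.gas.vsG_mean * geometry.cross_section       # m^3/s
    F_mix = mixing_flow(geometry, Q_gas)
    V_L = sol.M_L / props.rho_L
    V_G = sol.gas.eps_G * geometry.V_aerated

    r_O2 = -sol.R_O2_mol_h / sol.M_L
    r_S = -sol.R_S_mol_h / sol.M_L
    r_CO2 = sol.stoich.RQ * r_O2
    if min(r_O2, r_S, r_CO2) <= 0 or F_mix <= 0 or Q_gas <= 0:
        raise DegenerateDesignError("zero rate or flow: times undefined")

    q_heat = props.heat_per_O2 * sol.N_O2 / 3.6             # W/kg
    return CharacteristicTimes(
        tau_mix_L=strategies.mix_circulations * V_L / F_mix,
        tau_mix_G=(V_G / Q_gas) / strategies.gas_mixing_speedup,
        tau_FG=V_G / Q_gas,
        tau_S=sol.C_S / r_S * 3600.0,
        tau_O2=sol.op.C_O2_set / r_O2 * 3600.0,
        tau_CO2=sol.C_CO2 / r_CO2 * 3600.0,
        tau_heat=props.cp * 1000.0 * strategies.dT_allowed / q_heat)


def gradient_flags(times: CharacteristicTimes,
                   threshold: float = 10.0) -> list[GradientFlag]:
    """Mechanism pairs whose time-constant ratio exceeds ``threshold``.

    A mechanism much faster than mixing (ratio tau_mix/tau_mechanism above
    the threshold) can develop spatial gradients before the phase
    homogenises; with ``threshold = inf`` no pair is ever flagged.
    """
    pairs = [
        ("substrate consumption", "liquid mixing",
         times.tau_mix_L / times.tau_S),
        ("O2 consumption", "liquid mixing", times.tau_mix_L / times.tau_O2),
        ("CO2 production", "liquid mixing", times.tau_mix_L / times.tau_CO2),
        ("heat production", "liquid mixing", times.tau_mix_L / times.tau_heat),
        ("gas flow-through", "gas mixing", times.tau_FG / times.tau_mix_G),
    ]
    return [GradientFlag(mechanism=m, reference=ref, ratio=r)
            for m, ref, r in pairs if r > threshold]


def no2_top_bottom_ratio(sol: SteadyStateSolution,
                         props: PhysicalProperties = DEFAULT_PROPERTIES,
                         y_O2_out: float | None = None,
                         ) -> dict[str, float]:
    """Ratio of the O2 transfer driving force at the column bottom vs top.

    ``well_mixed`` uses the off-gas composition at both ends, leaving only
    the hydrostatic pressure difference; ``plug_flow`` exposes the bottom to
    the inlet composition, the upper bound of the transfer gradient.  Pass
    ``y_O2_out`` to probe hypothetical off-gas compositions.
    """
    op = sol.op
    y_out = sol.gas.y_O2 if y_O2_out is None else y_O2_out
    KH = henry_coefficient("O2", op.T, props)
    top = KH * y_out * op.p_top - op.C_O2_set
    if top <= 0:
        raise DomainError("no driving force at the top of the column")
    bot_mixed = KH * y_out * sol.gas.p_bot - op.C_O2_set
    bot_plug = KH * op.y_O2_in * sol.gas.p_bot - op.C_O2_set
    return {"well_mixed": bot_mixed / top, "plug_flow": bot_plug / top}
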