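"""Staged steady-state solver for the continuous SCP bubble column.

The chemostat fixes the process-reaction stoichiometry (hence the
CO2-production / O2-consumption ratio RQ) independently of the gas flow.
The gas-phase balances are then closed by a one-dimensional root find: for
a given top superficial velocity, the bottom superficial velocity is varied
until the O2 transfer rate implied by the total gas balance equals the rate
given by kLa times the driving force.  An outer bracketed iteration maps a
mean-velocity target onto the top velocity when the operating point is
specified by vsG_mean.

Once the gas side is converged, the liquid side follows sequentially: the
liquid mass from the hold-up, the outflow from the dilution rate, biomass
from the O2 conversion via the stoichiometry, and the feed flows and feed
substrate concentration from the liquid balances.

The staged scheme deliberately neglects dissolved CO2 leaving with the
liquid outflow (the CO2 production rate is equated to its transfer rate);
:func:`carbon_balance_error` quantifies the resulting surplus of carbon
leaving the reactor, and :func:`solve_simultaneous` provides the full
simultaneous solve of all balances, including that term, as a cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (DomainError, InfeasibleCompositionError,
                     NoSteadyStateError)
from .hydrodynamics import (DEFAULT_CORRELATIONS, CorrelationSet,
                            GasColumnState, ReactorGeometry, bottom_pressure,
                            effective_pressure, evaporation_rate, gas_holdup,
                            kla, log_mean, molar_flow)
from .properties import (DEFAULT_PROPERTIES, PhysicalProperties,
                         henry_coefficient)
from .stoichiometry import M_CO2, M_H2O, M_NH3, M_O2, ProcessStoichiometry

logger = logging.getLogger(__name__)

#: relative tolerance of the root finds on the superficial velocities
ROOT_RTOL = 1e-12


@dataclass(frozen=True)
class OperatingPoint:
    """Operational choices defining one steady state.

    Exactly one of ``vsG_mean`` / ``vsG_top`` must be given.  ``y_O2_in`` is
    1.0 for pure O2 or 0.21 for air (any value in between is a blend).
    """

    D: float = 0.15                      # dilution rate = mu, 1/h
    T_C: float = 30.0                    # broth temperature, C
    p_top: float = 1.2                   # overhead pressure, bar absolute
    y_O2_in: float = 1.0                 # inlet O2 mole fraction
    C_O2_set: float = 6.9e-5             # dissolved O2 setpoint, mol/kg_L
    C_NH3_residual: float = 1.0          # residual NH3 target, g/kg_L
    N_feed_concentration: float = 200.0  # NH3 feed strength, g/kg
    vsG_mean: float | None = 0.30        # m/s
    vsG_top: float | None = None         # m/s

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise DomainError("dilution rate must be positive")
        if not 0.0 < self.y_O2_in <= 1.0:
            raise DomainError("y_O2_in must be in (0, 1]")
        if (self.vsG_mean is None) == (self.vsG_top is None):
            raise DomainError(
                "specify exactly one of vsG_mean or vsG_top")
        v = self.vsG_mean if self.vsG_mean is not None else self.vsG_top
        if v <= 0:
            raise DomainError("superficial-velocity target must be positive")

    @property
    def T(self) -> float:
        """Broth temperature, K."""
        return self.T_C + 273.15


@dataclass
class SteadyStateSolution:
    """Complete converged operating point."""

    op: OperatingPoint
    stoich: ProcessStoichiometry
    gas: GasColumnState
    M_L: float                 # liquid (ungassed) mass, kg
    N_O2: float                # mol/(kg_L h), gas -> liquid positive
    N_CO2: float               # mol/(kg_L h)
    N_W: float                 # mol/(kg_L h)
    kla_O2: float              # 1/h
    kla_CO2: float             # 1/h
    p_eff: float               # driving-force pressure, bar
    C_x: float                 # dry biomass, g/kg_L
    C_x_mol: float             # mol_x/kg_L
    C_S: float                 # residual substrate, mol/kg_L
    C_CO2: float               # dissolved CO2, mol/kg_L
    C_NH3: float               # residual NH3, g/kg_L
    R_x_mol_h: float           # biomass production, mol/h
    R_x_kg_h: float            # biomass production, kg/h
    R_O2_mol_h: float          # O2 production (negative = consumption), mol/h
    R_S_mol_h: float           # substrate production (negative), mol/h
    R_NH3_mol_h: float         # NH3 production (negative), mol/h
    F_L_out: float             # liquid outflow, kg/h
    F_S_feed: float            # substrate feed stream, kg/h
    F_N_feed: float            # nitrogen-source feed stream, kg/h
    C_S_in: float              # feed substrate concentration, g/kg
    O2_utilization: float      # %
    ethanol_utilization: float  # %
    carbon_balance_error: float  # %
    residual: float            # leftover gas-phase objective, mol/(kg_L h)


# ---------------------------------------------------------------------------
# gas-phase residual


def _evaluate_gas(vsG_bot: float, vsG_top: float,
                  stoich: ProcessStoichiometry, op: OperatingPoint,
                  geometry: ReactorGeometry, props: PhysicalProperties,
                  corr: CorrelationSet) -> dict:
    """Evaluate the gas side for a (bottom, top) velocity pair.

    Returns the residual between the balance-derived and transfer-derived
    O2 fluxes together with every intermediate quantity.  The hold-up /
    bottom-pressure coupling is fully nested here (no stale values).
    """
    T = op.T
    RQ = stoich.RQ
    vm = log_mean(vsG_top, vsG_bot)
    eps = gas_holdup(vm, corr)
    p_bot = bottom_pressure(op.p_top, eps, geometry, props.rho_L)
    M_L = props.rho_L * (1.0 - eps) * geometry.V_aerated
    FG_in = molar_flow(vsG_bot, p_bot, T, geometry)
    FG_out = molar_flow(vsG_top, op.p_top, T, geometry)
    N_W, y_W = evaporation_rate(FG_out, op.p_top, T, M_L, props)

    # total gas balance, with the per-kg O2 consumption corrected for the
    # (small) dissolved-O2 outflow so the liquid balances close exactly:
    #   consumed/kg = N_O2 - D*C_O2_set;  N_CO2 = -RQ * consumed/kg
    N_bal = ((FG_in - FG_out) / M_L - N_W - RQ * op.D * op.C_O2_set) / (1.0 - RQ)
    N_CO2 = -RQ * (N_bal - op.D * op.C_O2_set)
    y_CO2 = -N_CO2 * M_L / FG_out
    y_N2 = FG_in * (1.0 - op.y_O2_in) / FG_out
    y_O2 = 1.0 - y_CO2 - y_N2 - y_W

    p_eff = effective_pressure(op.p_top, p_bot, corr)
    kla_O2 = kla(vm, op.T_C, "O2", props, corr, warn=False)
    c_eq = henry_coefficient("O2", T, props) * y_O2 * p_eff
    N_transfer = kla_O2 * (c_eq - op.C_O2_set)

    return dict(residual=N_bal - N_transfer, vsG_mean=vm, eps_G=eps,
                p_bot=p_bot, M_L=M_L, FG_in=FG_in, FG_out=FG_out,
                y_O2=y_O2, y_CO2=y_CO2, y_N2=y_N2, y_W=y_W,
                N_O2=N_bal, N_CO2=N_CO2, N_W=N_W, p_eff=p_eff,
                kla_O2=kla_O2)


def gas_phase_residual(vsG_bot: float, vsG_top: float,
                       stoich: ProcessStoichiometry, op: OperatingPoint,
                       geometry: ReactorGeometry = ReactorGeometry(),
                       props: PhysicalProperties = DEFAULT_PROPERTIES,
                       corr: CorrelationSet = DEFAULT_CORRELATIONS) -> float:
    """Objective of the gas-phase iteration, mol/(kg_L h).

    Difference between the O2 transfer rate implied by the gas balances and
    the one implied by kLa times the driving force; zero at steady state.
    """
    if vsG_bot <= 0 or vsG_top <= 0:
        raise DomainError("superficial velocities must be positive")
    out = _evaluate_gas(vsG_bot, vsG_top, stoich, op, geometry, props, corr)
    fractions = (out["y_O2"], out["y_CO2"], out["y_N2"], out["y_W"])
    if any(y < 0 for y in fractions):
        raise InfeasibleCompositionError(
            f"negative mole fraction in off-gas: O2={out['y_O2']:.4g}, "
            f"CO2={out['y_CO2']:.4g}, N2={out['y_N2']:.4g}, y_W={out['y_W']:.4g}")
    return out["residual"]


def _solve_bottom_velocity(vsG_top, stoich, op, geometry, props, corr):
    """Bracketed root find on vsG_bot at fixed vsG_top."""

    def f(vb):
        return _evaluate_gas(vb, vsG_top, stoich, op, geometry, props,
                             corr)["residual"]

    lo, hi = 0.2 * vsG_top, 5.0 * vsG_top
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        # widen and scan for a sign change before giving up
        grid = np.geomspace(0.01 * vsG_top, 5.0 * vsG_top, 60)
        vals = np.array([f(v) for v in grid])
        sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        if len(sign_change) == 0:
            raise NoSteadyStateError(
                f"no root of the gas-phase balance for vsG_top = {vsG_top:.4g}"
                " m/s: transfer cannot match the metabolic demand")
        lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    return optimize.brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)


def solve_operating_point(op: OperatingPoint, stoich: ProcessStoichiometry,
                          geometry: ReactorGeometry = ReactorGeometry(),
                          props: PhysicalProperties = DEFAULT_PROPERTIES,
                          corr: CorrelationSet = DEFAULT_CORRELATIONS,
                          ) -> SteadyStateSolution:
    """Converge one steady state and compute all liquid-side outputs.

    The stoichiometry must be evaluated at ``mu = op.D`` (chemostat).
    """
    if not math.isclose(stoich.mu, op.D, rel_tol=1e-9):
        raise DomainError(
            f"stoichiometry evaluated at mu = {stoich.mu}, but D = {op.D}")

    if op.vsG_top is not None:
        vsG_top = op.vsG_top
        vsG_bot = _solve_bottom_velocity(vsG_top, stoich, op, geometry,
                                         props, corr)
    else:
        target = op.vsG_mean

        def mean_error(vt):
            vb = _solve_bottom_velocity(vt, stoich, op, geometry, props, corr)
            return log_mean(vt, vb) - target

        lo, hi = 1.0005 * target, 4.0 * target
        if mean_error(hi) < 0:
            hi = 10.0 * target
            if mean_error(hi) < 0:
                raise NoSteadyStateError(
                    f"cannot reach vsG_mean = {target} m/s")
        vsG_top = optimize.brentq(mean_error, lo, hi, xtol=1e-14,
                                  rtol=ROOT_RTOL)
        vsG_bot = _solve_bottom_velocity(vsG_top, stoich, op, geometry,
                                         props, corr)

    out = _evaluate_gas(vsG_bot, vsG_top, stoich, op, geometry, props, corr)
    if out["N_O2"] <= 0:
        raise NoSteadyStateError(
            "converged to non-positive O2 transfer: no driving force above "
            "the dissolved-O2 setpoint")
    logger.info("converged vsG_top=%.4f vsG_bot=%.4f m/s, residual=%.3e",
                vsG_top, vsG_bot, out["residual"])
    return _liquid_side(out, vsG_top, vsG_bot, stoich, op, geometry, props,
                        corr)


def _liquid_side(out, vsG_top, vsG_bot, stoich, op, geometry, props, corr):
    """Sequential liquid-side calculation on a converged gas state."""
    M_L = out["M_L"]
    N_O2 = out["N_O2"]
    N_CO2 = out["N_CO2"]
    N_W = out["N_W"]
    F_L_out = op.D * M_L

    # O2 conversion -> biomass production via the stoichiometry
    R_O2_consumed = N_O2 * M_L - F_L_out * op.C_O2_set
    nu_O2_abs = -stoich.nu_O2
    R_x_mol = R_O2_consumed / nu_O2_abs
    M_x = stoich.biomass.molar_mass
    M_S = stoich.substrate.molar_mass
    R_x_kg = R_x_mol * M_x / 1000.0
    C_x = R_x_kg / F_L_out * 1000.0
    C_x_mol = R_x_mol / F_L_out

    # dissolved CO2 from the transfer-rate analogue
    kla_CO2 = kla(out["vsG_mean"], op.T_C, "CO2", props, corr)
    c_eq_co2 = henry_coefficient("CO2", op.T, props) * out["y_CO2"] * out["p_eff"]
    C_CO2 = c_eq_co2 - N_CO2 / kla_CO2

    R_S_mol = stoich.nu_S * R_x_mol          # negative
    R_NH3_mol = stoich.nu_NH3 * R_x_mol      # negative
    C_S = stoich.residual_CS
    C_S_g = C_S * M_S                        # g/kg

    F_N_feed = ((F_L_out * op.C_NH3_residual / 1000.0
                 + (-R_NH3_mol) * M_NH3 / 1000.0)
                / (op.N_feed_concentration / 1000.0))
    net_gas_mass = (N_O2 * M_O2 + N_CO2 * M_CO2 + N_W * M_H2O) * M_L / 1000.0
    F_S_feed = F_L_out - F_N_feed - net_gas_mass
    if F_S_feed <= 0:
        raise NoSteadyStateError("liquid balance gives non-positive feed flow")
    C_S_in = ((F_L_out * C_S_g + (-R_S_mol) * M_S) / F_S_feed)  # g/kg

    O2_util = N_O2 * M_L / (out["FG_in"] * op.y_O2_in) * 100.0
    eth_util = (1.0 - F_L_out * C_S_g / (F_S_feed * C_S_in)) * 100.0

    gas = GasColumnState(
        FG_N_in=out["FG_in"], FG_N_out=out["FG_out"],
        y_O2=out["y_O2"], y_CO2=out["y_CO2"], y_N2=out["y_N2"],
        y_W=out["y_W"], p_top=op.p_top, p_bot=out["p_bot"],
        vsG_top=vsG_top, vsG_bot=vsG_bot, vsG_mean=out["vsG_mean"],
        eps_G=out["eps_G"])

    sol = SteadyStateSolution(
        op=op, stoich=stoich, gas=gas, M_L=M_L,
        N_O2=N_O2, N_CO2=N_CO2, N_W=N_W,
        kla_O2=out["kla_O2"], kla_CO2=kla_CO2, p_eff=out["p_eff"],
        C_x=C_x, C_x_mol=C_x_mol, C_S=C_S, C_CO2=C_CO2,
        C_NH3=op.C_NH3_residual,
        R_x_mol_h=R_x_mol, R_x_kg_h=R_x_kg,
        R_O2_mol_h=-R_O2_consumed, R_S_mol_h=R_S_mol,
        R_NH3_mol_h=R_NH3_mol,
        F_L_out=F_L_out, F_S_feed=F_S_feed, F_N_feed=F_N_feed,
        C_S_in=C_S_in, O2_utilization=O2_util,
        ethanol_utilization=eth_util, carbon_balance_error=0.0,
        residual=out["residual"])
    sol.carbon_balance_error = carbon_balance_error(sol)
    return sol


def carbon_balance_error(sol: SteadyStateSolution) -> float:
    """Carbon surplus caused by neglecting dissolved CO2 in the outflow, %.

    The staged solver equates CO2 production with CO2 transfer, so the
    dissolved CO2 carried out with the liquid is carbon leaving the reactor
    on top of what the feed supplies.  Reported relative to the carbon fed
    with the substrate stream.
    """
    M_S = sol.stoich.substrate.molar_mass
    carbon_fed = (sol.F_S_feed * sol.C_S_in / M_S) * sol.stoich.substrate.C
    dissolved_out = sol.F_L_out * sol.C_CO2
    return dissolved_out / carbon_fed * 100.0


# ---------------------------------------------------------------------------
# balance verification

def material_balance_residuals(sol: SteadyStateSolution) -> dict[str, float]:
    """Relative residuals of the ten steady-state material balances.

    Evaluated exactly as implemented: the liquid O2 and ethanol balances
    carry the (small) dissolved outflow terms, while the liquid CO2 balance
    equates production and transfer (the staged approximation whose
    consequence :func:`carbon_balance_error` reports).
    """
    g, op, st = sol.gas, sol.op, sol.stoich
    M_S = st.substrate.molar_mass

    def rel(residual, scale):
        return abs(residual) / abs(scale)

    R_CO2 = st.nu_CO2 * sol.R_x_mol_h
    res = {
        "O2_gas": rel(g.FG_N_in * op.y_O2_in - g.FG_N_out * g.y_O2
                      - sol.N_O2 * sol.M_L, g.FG_N_in),
        "CO2_gas": rel(-g.FG_N_out * g.y_CO2 - sol.N_CO2 * sol.M_L,
                       g.FG_N_in),
        "N2_gas": rel(g.FG_N_in * (1.0 - op.y_O2_in) - g.FG_N_out * g.y_N2,
                      g.FG_N_in),
        "total_gas": rel(g.FG_N_in - g.FG_N_out
                         - (sol.N_O2 + sol.N_CO2 + sol.N_W) * sol.M_L,
                         g.FG_N_in),
        "O2_liquid": rel(sol.N_O2 * sol.M_L + sol.R_O2_mol_h
                         - sol.F_L_out * op.C_O2_set, sol.N_O2 * sol.M_L),
        "CO2_liquid": rel(sol.N_CO2 * sol.M_L + R_CO2, R_CO2),
        "substrate_liquid": rel(sol.F_S_feed * sol.C_S_in / 1000.0
                                - sol.F_L_out * sol.C_S * M_S / 1000.0
                                + sol.R_S_mol_h * M_S / 1000.0,
                                sol.F_S_feed * sol.C_S_in / 1000.0),
        "biomass_liquid": rel(sol.R_x_kg_h - sol.F_L_out * sol.C_x / 1000.0,
                              sol.R_x_kg_h),
        "NH3_liquid": rel(sol.F_N_feed * op.N_feed_concentration / 1000.0
                          - sol.F_L_out * sol.C_NH3 / 1000.0
                          + sol.R_NH3_mol_h * M_NH3 / 1000.0,
                          sol.F_N_feed * op.N_feed_concentration / 1000.0),
        "total_liquid": rel(sol.F_S_feed + sol.F_N_feed - sol.F_L_out
                            + (sol.N_O2 * M_O2 + sol.N_CO2 * M_CO2
                               + sol.N_W * M_H2O) * sol.M_L / 1000.0,
                            sol.F_L_out),
    }
    return res


# ---------------------------------------------------------------------------
# sweep

@dataclass
class SweepResult:
    table: pd.DataFrame
    solutions: list[SteadyStateSolution]
    failures: dict[float, str] = field(default_factory=dict)


_SWEEP_COLUMNS = ("vsG_mean", "FG_N_in", "FG_N_out", "M_L", "N_O2", "y_O2_out",
                  "C_CO2", "eps_G", "kla_O2", "O2_utilization", "C_x",
                  "R_x_kg_h", "C_S_in", "F_L_out", "carbon_balance_error")


def sweep(op: OperatingPoint, vsG_mean_grid: Sequence[float],
          stoich: ProcessStoichiometry,
          geometry: ReactorGeometry = ReactorGeometry(),
          props: PhysicalProperties = DEFAULT_PROPERTIES,
          corr: CorrelationSet = DEFAULT_CORRELATIONS) -> SweepResult:
    """Solve one operating point per mean-velocity grid value.

    Per-point failures are recorded in ``failures`` and the sweep continues.
    """
    rows, sols, failures = [], [], {}
    for v in vsG_mean_grid:
        try:
            point = replace(op, vsG_mean=float(v), vsG_top=None)
            sol = solve_operating_point(point, stoich, geometry, props, corr)
        except Exception as exc:  # noqa: BLE001 - recorded, sweep continues
            logger.warning("sweep point vsG_mean=%g failed: %s", v, exc)
            failures[float(v)] = str(exc)
            continue
        sols.append(sol)
        rows.append({
            "vsG_mean": sol.gas.vsG_mean, "FG_N_in": sol.gas.FG_N_in,
            "FG_N_out": sol.gas.FG_N_out, "M_L": sol.M_L, "N_O2": sol.N_O2,
            "y_O2_out": sol.gas.y_O2, "C_CO2": sol.C_CO2,
            "eps_G": sol.gas.eps_G, "kla_O2": sol.kla_O2,
            "O2_utilization": sol.O2_utilization, "C_x": sol.C_x,
            "R_x_kg_h": sol.R_x_kg_h, "C_S_in": sol.C_S_in,
            "F_L_out": sol.F_L_out,
            "carbon_balance_error": sol.carbon_balance_error})
    table = pd.DataFrame(rows, columns=list(_SWEEP_COLUMNS))
    return SweepResult(table=table, solutions=sols, failures=failures)


# ---------------------------------------------------------------------------
# simultaneous solve (cross-check; solves all balances at once, including
# the dissolved-CO2 outflow the staged scheme neglects)

@dataclass
class SimultaneousSolution:
    N_O2: float
    C_x: float
    C_CO2: float
    vsG_top: float
    vsG_bot: float
    y_O2: float
    y_CO2: float
    M_L: float
    success: bool


def solve_simultaneous(op: OperatingPoint, stoich: ProcessStoichiometry,
                       geometry: ReactorGeometry = ReactorGeometry(),
                       props: PhysicalProperties = DEFAULT_PROPERTIES,
                       corr: CorrelationSet = DEFAULT_CORRELATIONS,
                       x0: SteadyStateSolution | None = None,
                       ) -> SimultaneousSolution:
    """Solve every material balance as one nonlinear system.

    Unknowns: bottom/top velocities, off-gas O2 and CO2 fractions, the O2
    transfer rate and the dissolved CO2 concentration.  Unlike the staged
    scheme, the liquid CO2 balance retains the dissolved outflow term, so
    this route has no carbon-balance error.
    """
    T = op.T
    RQ = stoich.RQ
    KH_O2 = henry_coefficient("O2", T, props)
    KH_CO2 = henry_coefficient("CO2", T, props)

    target_mean = op.vsG_mean
    target_top = op.vsG_top

    def equations(x):
        vb, vt, y_O2, y_CO2, N_O2, C_CO2 = x
        vm = log_mean(vt, abs(vb))
        eps = gas_holdup(vm, corr)
        p_bot = bottom_pressure(op.p_top, eps, geometry, props.rho_L)
        M_L = props.rho_L * (1.0 - eps) * geometry.V_aerated
        FG_in = molar_flow(vb, p_bot, T, geometry)
        FG_out = molar_flow(vt, op.p_top, T, geometry)
        N_W, y_W = evaporation_rate(FG_out, op.p_top, T, M_L, props)
        F_L = op.D * M_L
        consumed = N_O2 * M_L - F_L * op.C_O2_set
        R_CO2 = RQ * consumed
        N_CO2 = -(R_CO2 - F_L * C_CO2) / M_L
        y_N2 = FG_in * (1.0 - op.y_O2_in) / FG_out
        p_eff = effective_pressure(op.p_top, p_bot, corr)
        kla_O2 = kla(vm, op.T_C, "O2", props, corr, warn=False)
        kla_CO2 = kla(vm, op.T_C, "CO2", props, corr, warn=False)
        vel_eq = (vm - target_mean) if target_mean is not None \
            else (vt - target_top)
        return [
            vel_eq,
            (FG_in - FG_out - (N_O2 + N_CO2 + N_W) * M_L) / FG_in,
            (FG_out * y_CO2 + N_CO2 * M_L) / FG_in,
            (N_O2 - kla_O2 * (KH_O2 * y_O2 * p_eff - op.C_O2_set)),
            (N_CO2 - kla_CO2 * (KH_CO2 * y_CO2 * p_eff - C_CO2)),
            y_O2 + y_CO2 + y_N2 + y_W - 1.0,
        ]

    if x0 is not None:
        guess = [x0.gas.vsG_bot, x0.gas.vsG_top, x0.gas.y_O2, x0.gas.y_CO2,
                 x0.N_O2, x0.C_CO2]
    else:
        v = target_mean if target_mean is not None else target_top
        guess = [0.6 * v, 1.4 * v, 0.8, 0.15, 0.5, 0.01]
    result = optimize.root(equations, guess, method="hybr",
                           options={"xtol": 1e-13})
    vb, vt, y_O2, y_CO2, N_O2, C_CO2 = result.x
    vm = log_mean(vt, vb)
    eps = gas_holdup(vm, corr)
    M_L = props.rho_L * (1.0 - eps) * geometry.V_aerated
    F_L = op.D * M_L
    consumed = N_O2 * M_L - F_L * op.C_O2_set
    C_x = consumed / (-stoich.nu_O2) * stoich.biomass.molar_mass / F_L
    return SimultaneousSolution(N_O2=N_O2, C_x=C_x, C_CO2=C_CO2,
                                vsG_top=vt, vsG_bot=vb, y_O2=y_O2,
                                y_CO2=y_CO2, M_L=M_L,
                                success=bool(result.success))
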