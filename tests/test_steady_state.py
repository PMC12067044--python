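"""Staged gas-phase solver, liquid-side outputs, and the simultaneous-solve
cross-check."""

import numpy as np
import pytest

import scpreactor as scp
from scpreactor.errors import DomainError, NoSteadyStateError


class TestResidual:
    def test_zero_at_converged_point(self, base_case, stoich):
        g = base_case.gas
        r = scp.gas_phase_residual(g.vsG_bot, g.vsG_top, stoich, base_case.op)
        assert abs(r) < 1e-9 * base_case.N_O2

    def test_single_sign_change_over_bracket(self, base_case, stoich):
        """The objective crosses zero exactly once around the solution."""
        g = base_case.gas
        grid = np.linspace(0.95 * g.vsG_bot, 1.2 * g.vsG_bot, 50)
        vals = [scp.gas_phase_residual(v, g.vsG_top, stoich, base_case.op)
                for v in grid]
        signs = np.sign(vals)
        changes = int(np.sum(signs[:-1] != signs[1:]))
        assert changes == 1

    def test_positive_velocities_required(self, stoich):
        with pytest.raises(DomainError):
            scp.gas_phase_residual(-0.1, 0.4, stoich, scp.OperatingPoint())


class TestBaseCase:
    """Converged pure-O2 operating points against the worked numbers."""

    def test_transfer_rate(self, base_case, low_velocity_case):
        assert base_case.N_O2 == pytest.approx(1.09, rel=0.05)
        assert low_velocity_case.N_O2 == pytest.approx(0.24, rel=0.05)

    def test_o2_utilization(self, base_case, low_velocity_case):
        assert base_case.O2_utilization == pytest.approx(27.0, rel=0.05)
        assert low_velocity_case.O2_utilization == pytest.approx(48.0, rel=0.05)

    def test_off_gas_composition(self, base_case, low_velocity_case):
        assert base_case.gas.y_O2 == pytest.approx(0.82, abs=0.02)
        assert low_velocity_case.gas.y_O2 == pytest.approx(0.67, abs=0.02)

    def test_biomass_concentration_and_production(self, base_case):
        assert base_case.C_x == pytest.approx(114.0, rel=0.05)
        assert base_case.R_x_kg_h == pytest.approx(7198.0, rel=0.05)

    def test_liquid_outflow_and_feed(self, base_case):
        assert base_case.F_L_out == pytest.approx(63e3, rel=0.05)
        assert base_case.C_S_in == pytest.approx(224.0, rel=0.05)
        assert base_case.F_N_feed == pytest.approx(5e3, rel=0.10)
        assert base_case.F_S_feed == pytest.approx(53e3, rel=0.05)

    def test_specific_ethanol_consumption(self, base_case):
        r_S = -base_case.R_S_mol_h / base_case.M_L
        assert r_S == pytest.approx(0.605, rel=0.05)

    def test_dissolved_co2(self, base_case, low_velocity_case):
        assert base_case.C_CO2 * 1e3 == pytest.approx(9.6, rel=0.07)
        assert low_velocity_case.C_CO2 * 1e3 == pytest.approx(20.0, rel=0.07)

    def test_ethanol_virtually_fully_utilized(self, base_case):
        assert base_case.ethanol_utilization > 99.9

    def test_mole_fractions_sum_to_one(self, base_case, low_velocity_case):
        for sol in (base_case, low_velocity_case):
            assert sol.gas.mole_fraction_sum() == pytest.approx(1.0, abs=1e-10)

    def test_velocity_target_met(self, base_case):
        assert base_case.gas.vsG_mean == pytest.approx(0.30, rel=1e-9)
        assert base_case.gas.vsG_bot < base_case.gas.vsG_mean \
            < base_case.gas.vsG_top

    def test_vsg_top_specification_mode(self, base_case, stoich):
        op = scp.OperatingPoint(vsG_mean=None, vsG_top=base_case.gas.vsG_top)
        sol = scp.solve_operating_point(op, stoich)
        assert sol.N_O2 == pytest.approx(base_case.N_O2, rel=1e-9)


class TestConservation:
    def test_all_material_balances_close(self, base_case, low_velocity_case):
        for sol in (base_case, low_velocity_case):
            for name, res in scp.material_balance_residuals(sol).items():
                assert res < 1e-9, name

    def test_gas_side_conservation(self, base_case):
        g = base_case.gas
        transferred = (base_case.N_O2 + base_case.N_CO2
                       + base_case.N_W) * base_case.M_L
        assert g.FG_N_in - g.FG_N_out == pytest.approx(
            transferred, rel=1e-9)

    def test_biomass_o2_proportionality_exact(self, base_case):
        """C_x D M_L / M_x equals the O2 conversion over |nu_O2| exactly."""
        lhs = (base_case.C_x / 1000.0 * base_case.op.D * base_case.M_L
               / base_case.stoich.biomass.molar_mass * 1000.0)
        rhs = -base_case.R_O2_mol_h / (-base_case.stoich.nu_O2)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestSimultaneousCrossCheck:
    @pytest.mark.parametrize("v", [0.04, 0.15, 0.30])
    def test_staged_agrees_with_simultaneous_solve(self, stoich, v):
        """Solving all balances at once (with dissolved-CO2 outflow) must
        agree with the staged scheme within its approximation error."""
        op = scp.OperatingPoint(vsG_mean=v)
        staged = scp.solve_operating_point(op, stoich)
        sim = scp.solve_simultaneous(op, stoich, x0=staged)
        assert sim.success
        tol = max(2.0 * staged.carbon_balance_error / 100.0, 1e-3)
        assert sim.N_O2 == pytest.approx(staged.N_O2, rel=tol)
        assert sim.C_x == pytest.approx(staged.C_x, rel=tol)
        assert sim.C_CO2 == pytest.approx(staged.C_CO2, rel=5 * tol)


class TestSweep:
    def test_liquid_mass_drops_21_percent(self, base_sweep):
        m = base_sweep.table["M_L"]
        drop = 1.0 - m.iloc[-1] / m.iloc[0]
        assert drop == pytest.approx(0.21, abs=0.01)

    def test_monotone_trends(self, base_sweep):
        t = base_sweep.table
        assert t["O2_utilization"].is_monotonic_decreasing
        assert t["N_O2"].is_monotonic_increasing
        assert t["kla_O2"].is_monotonic_increasing
        assert t["eps_G"].is_monotonic_increasing

    def test_off_gas_window(self, base_sweep):
        y = base_sweep.table["y_O2_out"]
        assert y.between(0.65, 0.84).all()

    def test_no_failures_on_base_grid(self, base_sweep):
        assert not base_sweep.failures
        assert len(base_sweep.solutions) == len(base_sweep.table)

    def test_failures_recorded_not_fatal(self, stoich):
        result = scp.sweep(scp.OperatingPoint(), [0.15, -1.0], stoich)
        assert len(result.solutions) == 1
        assert -1.0 in result.failures


class TestCarbonBalanceError:
    def test_positive_whenever_dissolved_co2_flows_out(self, base_case):
        assert base_case.C_CO2 > 0
        assert base_case.carbon_balance_error > 0

    def test_decreases_with_gas_velocity(self, base_sweep):
        assert base_sweep.table["carbon_balance_error"] \
            .is_monotonic_decreasing

    def test_zero_without_dissolved_co2(self, base_case):
        import copy
        sol = copy.copy(base_case)
        sol.C_CO2 = 0.0
        assert scp.carbon_balance_error(sol) == 0.0


class TestAirMode:
    def test_air_transfers_less_and_utilizes_less(self, base_case, stoich):
        air = scp.solve_operating_point(
            scp.OperatingPoint(vsG_mean=0.30, y_O2_in=0.21), stoich)
        assert air.N_O2 < base_case.N_O2
        assert air.O2_utilization < base_case.O2_utilization
        assert air.gas.y_N2 > 0.5
        for name, res in scp.material_balance_residuals(air).items():
            assert res < 1e-9, name

    def test_pure_o2_productivity_advantage(self, base_case, stoich):
        air = scp.solve_operating_point(
            scp.OperatingPoint(vsG_mean=0.30, y_O2_in=0.21), stoich)
        assert base_case.R_x_kg_h / air.R_x_kg_h > 3.0


def test_no_steady_state_when_demand_unreachable(stoich):
    """A dissolved-O2 setpoint near saturation leaves no driving force."""
    op = scp.OperatingPoint(vsG_mean=0.30, C_O2_set=2.5e-3)
    with pytest.raises(NoSteadyStateError):
        scp.solve_operating_point(op, stoich)


def test_operating_point_validation():
    with pytest.raises(DomainError):
        scp.OperatingPoint(vsG_mean=0.3, vsG_top=0.4)
    with pytest.raises(DomainError):
        scp.OperatingPoint(vsG_mean=None, vsG_top=None)
    with pytest.raises(DomainError):
        scp.OperatingPoint(y_O2_in=0.0)
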