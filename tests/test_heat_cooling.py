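"""Heat balance, cooling-loop sizing, and the cell-stress profile."""

import dataclasses

import pytest

import scpreactor as scp
from scpreactor.errors import DegenerateDesignError


class TestHeatBalance:
    def test_specific_heat_load(self, base_case):
        heat = scp.heat_balance(base_case)
        assert heat.specific_load == pytest.approx(139.0, rel=0.05)

    def test_cooling_duty_near_59_MW(self, base_cooling):
        heat, _ = base_cooling
        assert heat.Q_cool == pytest.approx(59e3, rel=0.05)  # kW

    def test_closure(self, base_cooling):
        heat, _ = base_cooling
        assert heat.Q_cool == pytest.approx(heat.Q_r - heat.Q_evap)

    def test_evaporation_below_5pct_of_reaction_heat(self, base_sweep):
        for sol in base_sweep.solutions:
            heat = scp.heat_balance(sol)
            assert 0 < heat.Q_evap < 0.05 * heat.Q_r

    def test_scales_linearly_with_transfer(self, base_case, low_velocity_case):
        h1 = scp.heat_balance(base_case)
        h2 = scp.heat_balance(low_velocity_case)
        r1 = h1.Q_r / (-base_case.R_O2_mol_h)
        r2 = h2.Q_r / (-low_velocity_case.R_O2_mol_h)
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestCoolingDesign:
    def test_required_area_and_unit_count(self, base_cooling):
        _, design = base_cooling
        assert design.A_cool == pytest.approx(2805.0, rel=0.05)
        assert design.n_exchangers == 7

    def test_loop_flow_and_passes(self, base_cooling):
        _, design = base_cooling
        assert design.F_cool == pytest.approx(939.0, rel=0.05)
        assert design.passes_per_hour == pytest.approx(8.0, rel=0.05)

    def test_loop_flow_closure_exact(self, base_cooling, props):
        heat, design = base_cooling
        assert design.F_cool * props.cp * design.dT_loop == pytest.approx(
            heat.Q_cool, rel=1e-12)

    def test_internal_coil_area(self, geometry):
        assert scp.coil_area(geometry) == pytest.approx(474.0, rel=0.01)

    def test_coil_insufficient_over_whole_sweep(self, base_sweep, geometry):
        """The quantitative case for the external loop: even at the lowest
        velocity the required area exceeds the internal coil."""
        for sol in base_sweep.solutions:
            heat = scp.heat_balance(sol)
            design = scp.size_cooling_system(heat, sol.M_L)
            assert design.A_cool > design.coil_area_available

    def test_tube_velocity(self, base_cooling):
        _, design = base_cooling
        assert design.tube_velocity == pytest.approx(0.41, rel=0.15)

    def test_zero_duty_design(self, base_cooling, geometry):
        heat = scp.HeatBalance(Q_r=0.0, Q_evap=0.0, Q_cool=0.0,
                               specific_load=0.0)
        design = scp.size_cooling_system(heat, 4e5)
        assert design.A_cool == 0.0
        assert design.n_exchangers == 0
        assert design.F_cool == 0.0


class TestStressProfile:
    @pytest.mark.parametrize("v, tau", [(0.41, 0.21), (1.6, 0.85)])
    def test_wall_shear_at_reference_velocities(self, v, tau):
        assert scp.wall_shear(v) == pytest.approx(tau, abs=0.01)

    def test_laminar_variant_is_eightfold(self):
        params = dataclasses.replace(scp.CoolingParameters(),
                                     wall_shear_model="laminar")
        assert scp.wall_shear(0.41, params) == pytest.approx(
            8.0 * scp.wall_shear(0.41), rel=1e-12)

    def test_pump_shear_range(self, base_case, base_cooling):
        _, design = base_cooling
        profile = scp.stress_profile(design, base_case)
        lo, hi = profile.pump_shear_range
        assert lo == pytest.approx(63.0, rel=0.02)
        assert hi == pytest.approx(628.0, rel=0.02)
        assert hi > lo  # shear increases with rotation speed

    def test_depletion_times_at_both_velocities(self, base_case,
                                                low_velocity_case,
                                                base_cooling):
        _, design = base_cooling
        fast = scp.stress_profile(design, base_case)
        assert fast.t_O2_depletion == pytest.approx(0.2, abs=0.05)
        assert fast.t_S_depletion == pytest.approx(6.6, rel=0.1)
        heat_lo = scp.heat_balance(low_velocity_case)
        design_lo = scp.size_cooling_system(heat_lo, low_velocity_case.M_L)
        slow = scp.stress_profile(design_lo, low_velocity_case)
        assert slow.t_O2_depletion == pytest.approx(1.0, rel=0.15)
        assert slow.t_S_depletion == pytest.approx(30.0, rel=0.1)

    def test_loop_residence_single_pass(self, base_case, base_cooling):
        _, design = base_cooling
        profile = scp.stress_profile(design, base_case)
        assert profile.t_loop_residence == pytest.approx(39.0, rel=0.1)

    def test_o2_depleted_within_the_loop(self, base_sweep):
        """Cells run out of dissolved O2 before completing one loop pass."""
        for sol in base_sweep.solutions:
            design = scp.size_cooling_system(scp.heat_balance(sol), sol.M_L)
            profile = scp.stress_profile(design, sol)
            assert profile.t_O2_depletion < profile.t_loop_residence

    def test_more_passes_raise_velocity_and_shear(self, base_case,
                                                  base_cooling):
        _, design = base_cooling
        one = scp.stress_profile(design, base_case, passes_in_tubes=1)
        four = scp.stress_profile(design, base_case, passes_in_tubes=4)
        assert four.tube_velocity == pytest.approx(4 * one.tube_velocity)
        assert four.wall_shear_tube > one.wall_shear_tube
        assert four.t_loop_residence < one.t_loop_residence

    def test_degenerate_design_rejected(self, base_case):
        heat = scp.HeatBalance(0.0, 0.0, 0.0, 0.0)
        design = scp.size_cooling_system(heat, base_case.M_L)
        with pytest.raises(DegenerateDesignError):
            scp.stress_profile(design, base_case)
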