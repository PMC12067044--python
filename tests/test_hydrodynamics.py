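"""Transfer and hold-up correlations, velocities, pressures, fluxes."""

import math

import numpy as np
import pytest

import scpreactor as scp
from scpreactor.errors import DomainError, SaturationError


class TestKla:
    @pytest.mark.parametrize("v, expected", [(0.30, 617.0), (0.04, 150.0)])
    def test_reference_values_at_30C(self, v, expected):
        assert scp.kla(v, 30.0) == pytest.approx(expected, abs=1.0)

    def test_temperature_factor_unity_at_20C(self):
        v = 0.1
        assert scp.kla(v, 20.0) == pytest.approx(0.32 * v**0.7 * 3600.0)

    def test_co2_correction_is_velocity_independent(self, props):
        expected = math.sqrt(props.co2_o2_diffusivity_ratio())
        for v in (0.05, 0.15, 0.30):
            ratio = scp.kla(v, 30.0, "CO2") / scp.kla(v, 30.0, "O2")
            assert ratio == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_sublinear(self):
        vs = np.linspace(0.04, 0.30, 10)
        ks = [scp.kla(v, 30.0) for v in vs]
        assert all(b > a for a, b in zip(ks, ks[1:]))
        # sublinear: kLa per unit velocity falls as velocity rises
        per_v = [k / v for k, v in zip(ks, vs)]
        assert all(b < a for a, b in zip(per_v, per_v[1:]))

    def test_warns_outside_validity_window(self):
        with pytest.warns(UserWarning):
            scp.kla(0.5, 30.0)
        with pytest.raises(DomainError):
            scp.kla(-0.1, 30.0)


class TestHoldup:
    @pytest.mark.parametrize("v, expected", [(0.30, 0.26), (0.04, 0.06)])
    def test_reference_values(self, v, expected):
        assert scp.gas_holdup(v) == pytest.approx(expected, abs=0.005)

    def test_zero_velocity(self):
        assert scp.gas_holdup(0.0) == 0.0

    def test_capped_below_one(self):
        assert scp.gas_holdup(50.0) < 1.0


class TestVelocities:
    def test_round_trip(self, geometry):
        for v in (0.01, 0.1, 0.45):
            f = scp.molar_flow(v, 1.7, 303.15, geometry)
            assert scp.superficial_velocity(f, 1.7, 303.15, geometry) == \
                pytest.approx(v, rel=1e-14)

    def test_single_line_oracle(self, geometry):
        # 1 mol/s at 1 bar, 303.15 K through a 5.03 m diameter column
        v = scp.superficial_velocity(3600.0, 1.0, 303.15, geometry)
        expected = (8.314462618 * 303.15 / 1e5) / (math.pi / 4 * 5.03**2)
        assert v == pytest.approx(expected, rel=1e-3)

    def test_doubling_pressure_halves_velocity(self, geometry):
        v1 = scp.superficial_velocity(1e5, 1.0, 303.15, geometry)
        v2 = scp.superficial_velocity(1e5, 2.0, 303.15, geometry)
        assert v1 == pytest.approx(2.0 * v2, rel=1e-14)

    def test_pressure_domain(self, geometry):
        with pytest.raises(DomainError):
            scp.superficial_velocity(1.0, -1.0, 303.15, geometry)


class TestLogMean:
    def test_closed_form(self):
        assert scp.log_mean(0.3, 0.1) == pytest.approx(0.2 / math.log(3.0))

    def test_equal_inputs_limit(self):
        assert scp.log_mean(0.2, 0.2) == pytest.approx(0.2)

    def test_between_min_and_max(self):
        rng = np.random.default_rng(42)
        for a, b in rng.uniform(0.01, 2.0, size=(50, 2)):
            m = scp.log_mean(a, b)
            assert min(a, b) <= m <= max(a, b)

    def test_domain(self):
        with pytest.raises(DomainError):
            scp.log_mean(-0.1, 0.2)


class TestBottomPressure:
    def test_single_line_oracle(self, geometry):
        # 1000 kg/m3 * (1-0.26) * g * (0.95 * 30.2 m) hydrostatic head
        p = scp.bottom_pressure(1.2, 0.26, geometry)
        head = 1000 * 0.74 * 9.80665 * geometry.H_aerated / 1e5
        assert p == pytest.approx(1.2 + head)
        assert p == pytest.approx(3.28, abs=0.03)

    def test_zero_column(self):
        g0 = scp.ReactorGeometry(V_R=1e-12)
        assert scp.bottom_pressure(1.2, 0.0, g0) == pytest.approx(1.2, abs=1e-4)

    def test_decreasing_in_holdup(self, geometry):
        ps = [scp.bottom_pressure(1.2, e, geometry)
              for e in np.linspace(0.0, 0.5, 10)]
        assert all(b < a for a, b in zip(ps, ps[1:]))


class TestTransferAndEvaporation:
    def test_zero_at_equilibrium(self, props):
        KH = scp.henry_coefficient("O2", 303.15)
        c_star = KH * 0.8 * 2.0
        assert scp.transfer_rate("O2", 0.8, 2.0, c_star, 600.0, 303.15) == \
            pytest.approx(0.0, abs=1e-15)

    def test_driving_force_identity(self):
        # N = kLa * driving force, so N/kLa recovers the driving force
        n = scp.transfer_rate("O2", 0.82, 2.07, 6.9e-5, 617.0, 303.15)
        KH = scp.henry_coefficient("O2", 303.15)
        assert n / 617.0 == pytest.approx(KH * 0.82 * 2.07 - 6.9e-5)

    def test_negative_transfer_is_legal(self):
        # CO2 leaves a supersaturated liquid
        n = scp.transfer_rate("CO2", 0.01, 1.2, 0.02, 590.0, 303.15)
        assert n < 0

    def test_evaporation_scales_linearly_with_gas_flow(self):
        n1, y1 = scp.evaporation_rate(1e6, 1.2, 303.15, 4e5)
        n2, y2 = scp.evaporation_rate(2e6, 1.2, 303.15, 4e5)
        assert n1 < 0 and y1 == y2
        assert n2 == pytest.approx(2.0 * n1)

    def test_equilibrium_fraction(self):
        _, y = scp.evaporation_rate(1e6, 1.2, 303.15, 4e5)
        assert y == pytest.approx(scp.water_vapor_pressure(303.15) / 1.2)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            scp.evaporation_rate(1e6, 0.03, 303.15, 4e5)


def test_geometry_from_volume_and_aspect_ratio(geometry):
    assert geometry.D_R == pytest.approx(5.03, abs=0.005)
    assert geometry.H_R == pytest.approx(6 * geometry.D_R)
    with pytest.raises(DomainError):
        scp.ReactorGeometry(fill_fraction=1.2)
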