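import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbreactor import (DispersionCorrelation, FluidProperties,
                       InvalidInputError, ReactorSpec,
                       axial_dispersion_coefficient, interstitial_velocity,
                       residence_time, reynolds_number, superficial_velocity)
from pbreactor.units import ml_min_to_m3_s

ML_MIN_5 = ml_min_to_m3_s(5.0)


class TestReactorSpec:
    def test_defaults_are_the_bench_column(self, spec):
        assert spec.length_m == pytest.approx(0.05)
        assert spec.diameter_m == pytest.approx(0.004)
        assert spec.volume_m3 == pytest.approx(0.628e-6)
        assert spec.aspect_ratio == pytest.approx(12.5)
        assert spec.enzyme_mass_g == pytest.approx(0.27)

    @pytest.mark.parametrize("field,value", [
        ("length_m", -0.05), ("length_m", 0.0), ("void_fraction", 0.0),
        ("void_fraction", 1.0), ("void_fraction", 1.5),
        ("particle_diameter_m", 0.005),  # larger than the column bore
        ("enzyme_mass_kg", 0.0),
    ])
    def test_invalid_geometry_rejected(self, field, value):
        kwargs = {field: value}
        with pytest.raises(InvalidInputError):
            ReactorSpec(**kwargs)

    def test_volume_inconsistent_with_cylinder_rejected(self):
        with pytest.raises(InvalidInputError, match="inconsistent"):
            ReactorSpec(volume_m3=0.8e-6)  # 27% off pi*D^2*L/4


class TestSuperficialVelocity:
    def test_five_ml_min_in_default_column(self, spec):
        # 4Q/(pi*D^2) with Q = 5 mL/min, D = 0.4 cm
        assert superficial_velocity(ML_MIN_5, spec) == pytest.approx(6.63e-3,
                                                                     rel=1e-3)

    def test_linear_in_flow(self, spec):
        assert superficial_velocity(ml_min_to_m3_s(0.5), spec) == pytest.approx(
            superficial_velocity(ML_MIN_5, spec) / 10.0)

    def test_doubling_diameter_quarters_velocity(self, spec):
        wide = ReactorSpec(diameter_m=2 * spec.diameter_m,
                           volume_m3=4 * spec.volume_m3)
        assert superficial_velocity(ML_MIN_5, wide) == pytest.approx(
            superficial_velocity(ML_MIN_5, spec) / 4.0)

    def test_nonpositive_flow_rejected(self, spec):
        with pytest.raises(InvalidInputError):
            superficial_velocity(0.0, spec)


class TestInterstitialVelocity:
    def test_matches_printed_value(self, spec):
        u0 = superficial_velocity(ML_MIN_5, spec)
        assert interstitial_velocity(u0, 0.3) == pytest.approx(0.022, rel=1e-2)

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.1, 1.2])
    def test_void_fraction_domain(self, eps):
        with pytest.raises(InvalidInputError):
            interstitial_velocity(1e-3, eps)

    def test_zero_velocity_passes_through(self):
        assert interstitial_velocity(0.0, 0.3) == 0.0


class TestResidenceTime:
    def test_base_point_rounds_to_printed_value(self, spec):
        tau_min = residence_time(spec, ML_MIN_5) / 60.0
        assert tau_min == pytest.approx(0.0377, rel=1e-2)
        assert round(tau_min, 2) == 0.04

    def test_one_minute_regime_within_pump_range(self, spec):
        # eps*V/Q: tau ~ 1 min at 0.19 mL/min, inside the 0.1-1.0 mL/min pump
        tau_min = residence_time(spec, ml_min_to_m3_s(0.19)) / 60.0
        assert tau_min == pytest.approx(1.0, rel=1e-2)

    def test_decreases_with_flow(self, spec):
        taus = [residence_time(spec, ml_min_to_m3_s(q)) for q in (0.1, 1, 5, 50)]
        assert all(a > b for a, b in zip(taus, taus[1:]))

    def test_nonpositive_flow_rejected(self, spec):
        with pytest.raises(InvalidInputError):
            residence_time(spec, -1e-8)


class TestReynoldsNumber:
    def test_matches_printed_value(self, spec, fluid):
        u0 = superficial_velocity(ML_MIN_5, spec)
        assert reynolds_number(spec, u0, fluid) == pytest.approx(7.69, rel=2e-3)

    def test_doubling_viscosity_halves(self, spec, fluid):
        u0 = superficial_velocity(ML_MIN_5, spec)
        thick = FluidProperties(density_kg_m3=fluid.density_kg_m3,
                                viscosity_pa_s=2 * fluid.viscosity_pa_s)
        assert reynolds_number(spec, u0, thick) == pytest.approx(
            reynolds_number(spec, u0, fluid) / 2.0)

    def test_zero_velocity_gives_zero(self, spec, fluid):
        assert reynolds_number(spec, 0.0, fluid) == 0.0

    def test_zero_viscosity_rejected(self):
        with pytest.raises(InvalidInputError):
            FluidProperties(viscosity_pa_s=0.0)


class TestDispersionCoefficient:
    def test_anchor_reproduces_printed_dz(self, spec, fluid):
        u0 = superficial_velocity(ML_MIN_5, spec)
        re = reynolds_number(spec, u0, fluid)
        dz = axial_dispersion_coefficient(re, u0, spec.void_fraction,
                                          spec.particle_diameter_m,
                                          DispersionCorrelation())
        assert dz == pytest.approx(2.21e-5, rel=1e-2)

    def test_single_point_constant_extrapolation(self, spec):
        corr = DispersionCorrelation(reynolds=(7.69,), group=(3.5,))
        for re in (0.1, 7.69, 500.0):
            dz = axial_dispersion_coefficient(re, 1e-3, 0.3, 5e-4, corr)
            assert dz == pytest.approx(3.5 * 1e-3 * 5e-4 / 0.3)

    def test_interpolation_hits_knots(self):
        corr = DispersionCorrelation(reynolds=(1.0, 10.0, 100.0),
                                     group=(0.5, 2.0, 8.0))
        for re, g in zip(corr.reynolds, corr.group):
            assert corr.evaluate(re) == pytest.approx(g)

    def test_loglog_interpolation_between_knots(self):
        # power-law table: log-log interpolation is exact on it
        corr = DispersionCorrelation(reynolds=(1.0, 100.0), group=(1.0, 10.0))
        assert corr.evaluate(10.0) == pytest.approx(math.sqrt(10.0))

    def test_empty_or_unsorted_table_rejected(self):
        from pbreactor import ConfigError
        with pytest.raises(ConfigError):
            DispersionCorrelation(reynolds=(), group=())
        with pytest.raises(ConfigError):
            DispersionCorrelation(reynolds=(2.0, 1.0), group=(1.0, 1.0))

    def test_group_roundtrip(self, spec):
        corr = DispersionCorrelation(reynolds=(1.0, 50.0), group=(0.7, 4.0))
        u0, eps, dp = 2e-3, 0.4, 3e-4
        dz = axial_dispersion_coefficient(12.0, u0, eps, dp, corr)
        assert dz * eps / (u0 * dp) == pytest.approx(corr.evaluate(12.0),
                                                     rel=1e-12)


@settings(max_examples=100, deadline=None)
@given(q=st.floats(1e-9, 1e-5), eps=st.floats(0.05, 0.95))
def test_tau_times_u_equals_length(q, eps):
    """tau * u = L when V is exactly the cylinder volume (here: to the 2%
    slack the stated total volume is allowed)."""
    spec = ReactorSpec(void_fraction=eps)
    u = interstitial_velocity(superficial_velocity(q, spec), eps)
    assert residence_time(spec, q) * u == pytest.approx(spec.length_m,
                                                        rel=0.02)


@settings(max_examples=60, deadline=None)
@given(q=st.floats(1e-9, 1e-5), factor=st.floats(1.1, 10.0))
def test_transport_monotonicities(q, factor, spec, fluid):
    u0 = superficial_velocity(q, spec)
    assert superficial_velocity(q * factor, spec) > u0
    assert interstitial_velocity(u0 * factor, 0.3) > interstitial_velocity(u0, 0.3)
    assert residence_time(spec, q * factor) < residence_time(spec, q)
    assert reynolds_number(spec, u0 * factor, fluid) > reynolds_number(spec, u0, fluid)
    corr = DispersionCorrelation()
    assert axial_dispersion_coefficient(5.0, u0 * factor, 0.3, 5e-4, corr) > \
        axial_dispersion_coefficient(5.0, u0, 0.3, 5e-4, corr)
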