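from dataclasses import replace

import numpy as np
import pytest

from pbreactor import (InvalidInputError, PingPongParams, SolverError,
                       solve_axial_dispersion, solve_finite_difference,
                       solve_plug_flow, sweep)
from pbreactor.kinetics import _rate_clamped, volumetric_rate
from pbreactor.model import ModelConfig, OperatingPoint, Scenario


def tiny_kinetics():
    """Effectively reaction-free kinetics (Vmax vanishingly small)."""
    return PingPongParams(vmax_mmol_g_min=1e-12)


class TestModelConfigValidation:
    def test_minimum_grid(self, base_cfg):
        with pytest.raises(InvalidInputError):
            replace(base_cfg, n_nodes=5)

    def test_negative_dispersion_rejected(self, base_cfg):
        with pytest.raises(InvalidInputError):
            replace(base_cfg, dz_m2_s=-1e-6)

    def test_zero_dispersion_needs_plug_flow_solver(self, base_cfg):
        cfg = replace(base_cfg, dz_m2_s=0.0)
        with pytest.raises(InvalidInputError):
            solve_axial_dispersion(cfg)

    def test_unknown_inlet_bc_rejected(self, base_cfg):
        from pbreactor import ConfigError
        with pytest.raises(ConfigError):
            replace(base_cfg, inlet_bc="periodic")


class TestNoReactionLimit:
    def test_dispersion_profile_constant(self, base_cfg):
        cfg = replace(base_cfg, kinetics=tiny_kinetics())
        profile = solve_axial_dispersion(cfg)
        assert profile.cr_mM == pytest.approx(cfg.cr0_mM, abs=1e-6)
        assert profile.ca_mM == pytest.approx(cfg.ca0_mM, abs=1e-6)

    def test_plug_flow_profile_constant(self, base_cfg):
        cfg = replace(base_cfg, kinetics=tiny_kinetics())
        profile = solve_plug_flow(cfg)
        assert profile.cr_mM == pytest.approx(cfg.cr0_mM, abs=1e-6)


class TestPlugFlow:
    def test_matches_fixed_step_rk4_oracle(self, base_cfg):
        """Independent fixed-step RK4 with Richardson step-halving agrees to
        six significant digits."""
        cfg = base_cfg
        delta = cfg.ca0_mM - cfg.cr0_mM
        contact = cfg.length_m / cfg.velocity_m_s

        def f(c):
            return -contact * volumetric_rate(
                _rate_clamped(c, c + delta, cfg.kinetics), cfg.spec)

        def rk4(n_steps):
            h = 1.0 / n_steps
            c = cfg.cr0_mM
            for _ in range(n_steps):
                k1 = f(c)
                k2 = f(c + 0.5 * h * k1)
                k3 = f(c + 0.5 * h * k2)
                k4 = f(c + h * k3)
                c += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            return float(c)

    # step halving: RK4 self-consistent to far better than 6 digits
        coarse, fine = rk4(2000), rk4(4000)
        assert fine == pytest.approx(coarse, rel=1e-8)
        assert solve_plug_flow(cfg).outlet_cr_mM == pytest.approx(fine, rel=1e-6)

    def test_consumption_linear_in_residence_time_at_trace_feed(self, scenario):
        # 1 mM trace feed at high flow: consumption ~ tau to first order
        op = OperatingPoint.equimolar(500.0, 2.0)
        cfg = scenario.model_config(op)
        slow = solve_plug_flow(cfg)
        fast = solve_plug_flow(replace(cfg, velocity_m_s=2 * cfg.velocity_m_s))
        consumed_slow = cfg.cr0_mM - slow.outlet_cr_mM
        consumed_fast = cfg.cr0_mM - fast.outlet_cr_mM
        assert consumed_fast == pytest.approx(consumed_slow / 2.0, rel=0.05)


class TestAxialDispersionSolver:
    def test_agrees_with_finite_difference_oracle(self, base_cfg, base_profile):
        oracle = solve_finite_difference(base_cfg)
        assert abs(base_profile.outlet_cr_mM - oracle.outlet_cr_mM) \
            <= 0.01 * base_cfg.cr0_mM
        # magnitude sanity: tens of mM survive the bed at 5 mL/min
        assert 20.0 < base_profile.outlet_cr_mM < 100.0

    def test_boundary_conditions_satisfied(self, base_cfg, base_profile):
        p = base_profile
        assert p.cr_mM[0] == pytest.approx(base_cfg.cr0_mM, rel=1e-8)
        assert p.ca_mM[0] == pytest.approx(base_cfg.ca0_mM, rel=1e-8)
        grad = (p.cr_mM[-1] - p.cr_mM[-2]) / (p.z_m[-1] - p.z_m[-2])
        assert abs(grad) <= 1e-2 * base_cfg.cr0_mM / base_cfg.length_m

    def test_stoichiometric_conservation(self, base_cfg, base_profile):
        assert base_profile.conservation_defect_mM() <= 1e-3 * base_cfg.cr0_mM

    def test_profile_monotone_nonincreasing(self, base_profile):
        assert np.all(np.diff(base_profile.cr_mM) <= 1e-9)
        assert np.all(base_profile.cr_mM >= 0.0)
        assert np.all(base_profile.cs_mM == base_profile.cs_mM[0])

    def test_mesh_independence(self, base_cfg, base_profile):
        finer = solve_axial_dispersion(replace(base_cfg,
                                               n_nodes=2 * base_cfg.n_nodes))
        assert finer.outlet_cr_mM == pytest.approx(base_profile.outlet_cr_mM,
                                                   rel=1e-3)

    def test_low_dispersion_approaches_plug_flow(self, base_cfg):
        pf = solve_plug_flow(base_cfg).outlet_cr_mM
        near = solve_axial_dispersion(replace(base_cfg, dz_m2_s=1e-7))
        assert near.outlet_cr_mM == pytest.approx(pf, rel=0.01)

    def test_danckwerts_inlet_option(self, base_cfg, base_profile):
        dw = solve_axial_dispersion(replace(base_cfg, inlet_bc="danckwerts"))
        # flux inlet lowers C(0) below C0, so the two solutions must differ
        assert dw.outlet_cr_mM != pytest.approx(base_profile.outlet_cr_mM,
                                                rel=1e-4)
        assert dw.conservation_defect_mM() <= 1e-3 * base_cfg.cr0_mM

    @pytest.mark.parametrize("flow,load", [(1.0, 150.0), (5.0, 500.0)])
    def test_oracle_agreement_off_base(self, scenario, flow, load):
        cfg = scenario.model_config(OperatingPoint.equimolar(flow, load))
        a = solve_axial_dispersion(cfg)
        b = solve_finite_difference(cfg)
        assert abs(a.outlet_cr_mM - b.outlet_cr_mM) <= 5e-3 * cfg.cr0_mM


class TestSweep:
    def test_conversion_monotone_in_flow(self, scenario, base_op):
        table = sweep(scenario, base_op, "flow_mL_min", [0.75, 1.5, 3.0, 5.0])
        assert list(table["value"]) == [0.75, 1.5, 3.0, 5.0]
        assert np.all(np.diff(table["conversion_pct"]) < 0)
        assert np.all(np.diff(table["tau_min"]) < 0)

    def test_single_value_sweep_equals_direct_solve(self, scenario, base_op,
                                                    base_profile):
        table = sweep(scenario, base_op, "flow_mL_min", [5.0])
        assert table.loc[0, "CR_out_mM"] == pytest.approx(
            base_profile.outlet_cr_mM, rel=1e-6)

    def test_concentration_study_design(self, scenario, base_op):
        # equimolar loads at 5 mL/min, the concentration-effect design
        loads = [100.0, 150.0, 200.0, 500.0]
        table = sweep(scenario, base_op, "load_mM", loads)
        assert list(table["value"]) == loads
        assert (table["conversion_pct"] > 0).all()
        assert (table["eeS_pct"].between(0, 100)).all()

    def test_invalid_values_rejected(self, scenario, base_op):
        with pytest.raises(InvalidInputError):
            sweep(scenario, base_op, "flow_mL_min", [])
        with pytest.raises(InvalidInputError):
            sweep(scenario, base_op, "flow_mL_min", [1.0, -2.0])
        with pytest.raises(InvalidInputError):
            sweep(scenario, base_op, "temperature", [30.0])
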