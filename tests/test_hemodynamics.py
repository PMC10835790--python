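"""Network solver tests: stress inversion, profiles, routing, Windkessel."""

import numpy as np
import pytest

from conftest import poiseuille_wall_shear
from iliacshear.cohort import FlowWaveform, control_template, make_virtual_patient, subject_template
from iliacshear.errors import ConfigurationError, DomainError, InvalidParameterError
from iliacshear.hemodynamics import (
    SolverOptions,
    TubeLaw,
    WindkesselParams,
    invert_stress,
    route_flows,
    simulate_patient,
    solve_generalized_poiseuille,
    tune_windkessel,
    windkessel_pressure,
)
from iliacshear.rheology import BLOOD, RheologyParams, shear_stress
from iliacshear.units import l_min_to_mm3s, mmhg_to_pa, pa_to_mmhg

# 200-step arbitrary-precision bisection of mu(g)*g = 1 Pa, blood params
GAMMA_AT_1PA = 258.14800385147790
# grid-refinement sequence (n_r 129 -> 8193) for Q = 0.635 L/min, R = 4.8 mm
WALL_SHEAR_SUBJECT_LCIV = 127.137509


def constant_waveform(q: float, period: float = 3.2, n: int = 64) -> FlowWaveform:
    t = np.arange(n) * period / n
    return FlowWaveform(period, t, np.full(n, q))


class TestInvertStress:
    def test_zero(self):
        assert invert_stress(0.0, BLOOD) == 0.0

    def test_newtonian(self):
        newt = RheologyParams.newtonian(0.0035)
        assert invert_stress(3.5, newt) == pytest.approx(1000.0, rel=1e-10)

    def test_frozen_value_and_round_trip(self):
        g = invert_stress(1.0, BLOOD)
        assert g == pytest.approx(GAMMA_AT_1PA, rel=1e-10)
        assert shear_stress(g, BLOOD) == pytest.approx(1.0, rel=1e-8)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            invert_stress(-0.1, BLOOD)


class TestGeneralizedPoiseuille:
    def test_newtonian_closed_form(self, newtonian):
        q, radius = 16_666.7, 5.0
        prof = solve_generalized_poiseuille(q, radius, newtonian)
        assert prof.wall_shear_rate == pytest.approx(poiseuille_wall_shear(q, radius), rel=1e-6)
        u_exact = 2 * q / (np.pi * radius**2) * (1 - (prof.radius_grid / radius) ** 2)
        assert prof.axial_velocity == pytest.approx(u_exact, rel=1e-6, abs=1e-6 * u_exact[0])
        assert prof.integrate_flow() == pytest.approx(q, rel=1e-6)

    def test_zero_flow(self):
        prof = solve_generalized_poiseuille(0.0, 4.0, BLOOD)
        assert prof.pressure_gradient == 0.0
        assert np.all(prof.axial_velocity == 0.0)
        assert np.all(prof.shear_rate == 0.0)

    def test_frozen_subject_scale_wall_shear(self):
        prof = solve_generalized_poiseuille(l_min_to_mm3s(0.635), 4.8, BLOOD)
        assert prof.wall_shear_rate == pytest.approx(WALL_SHEAR_SUBJECT_LCIV, rel=1e-6)
        assert prof.integrate_flow() == pytest.approx(l_min_to_mm3s(0.635), rel=1e-6)

    def test_no_slip_and_monotone_profile(self):
        prof = solve_generalized_poiseuille(8000.0, 4.0, BLOOD)
        assert prof.axial_velocity[-1] == 0.0
        assert np.all(np.diff(prof.axial_velocity) <= 1e-12)

    def test_grid_convergence_of_wall_shear(self):
        q, radius = 9000.0, 4.5
        g128 = solve_generalized_poiseuille(q, radius, BLOOD, 128).wall_shear_rate
        g256 = solve_generalized_poiseuille(q, radius, BLOOD, 256).wall_shear_rate
        assert abs(g256 / g128 - 1) < 1e-3

    def test_invalid_arguments(self):
        with pytest.raises(InvalidParameterError):
            solve_generalized_poiseuille(-1.0, 4.0, BLOOD)
        with pytest.raises(InvalidParameterError):
            solve_generalized_poiseuille(100.0, 4.0, BLOOD, n_radial=8)

    @pytest.mark.parametrize("q,radius", [(100.0, 2.0), (5000.0, 4.0), (20000.0, 7.0)])
    def test_tube_law_matches_direct_solve(self, q, radius):
        law = TubeLaw(BLOOD)
        direct = solve_generalized_poiseuille(q, radius, BLOOD, 513)
        assert law.wall_shear_rate(q, radius) == pytest.approx(
            direct.wall_shear_rate, rel=1e-6
        )


class TestRouteFlows:
    def test_constant_arithmetic(self):
        inflows = {
            name: constant_waveform(q)
            for name, q in zip(("REIV", "LEIV", "RIIV", "LIIV"), (1.0, 2.0, 3.0, 4.0))
        }
        routed = route_flows(inflows)
        assert routed["RCIV"].flows == pytest.approx(4.0)  # 1 + 3
        assert routed["LCIV"].flows == pytest.approx(6.0)  # 2 + 4
        assert routed["IVC"].flows == pytest.approx(10.0)

    def test_junction_conservation_pointwise(self):
        p = make_virtual_patient(subject_template(), 4)
        routed = route_flows(p.inflows)
        assert routed["IVC"].flows == pytest.approx(
            routed["RCIV"].flows + routed["LCIV"].flows, rel=1e-12
        )
        assert routed["RCIV"].flows == pytest.approx(
            routed["REIV"].flows + routed["RIIV"].flows, rel=1e-12
        )

    def test_subject_average_leg_flows_sum_to_ivc(self):
        inflows = {
            "REIV": constant_waveform(l_min_to_mm3s(1.46 * 0.7)),
            "RIIV": constant_waveform(l_min_to_mm3s(1.46 * 0.3)),
            "LEIV": constant_waveform(l_min_to_mm3s(0.73 * 0.7)),
            "LIIV": constant_waveform(l_min_to_mm3s(0.73 * 0.3)),
        }
        routed = route_flows(inflows)
        assert routed["IVC"].mean_flow() == pytest.approx(l_min_to_mm3s(2.19), rel=1e-9)

    def test_mismatched_periods_rejected(self):
        inflows = {n: constant_waveform(1.0) for n in ("REIV", "LEIV", "RIIV")}
        inflows["LIIV"] = constant_waveform(1.0, period=3.0)
        with pytest.raises(ConfigurationError):
            route_flows(inflows)


class TestWindkessel:
    WK_SUBJECT = WindkesselParams(r_proximal=0.00187, capacitance=22.4, r_distal=0.0355)

    def test_constant_flow_fixed_point_exact(self):
        q = l_min_to_mm3s(2.19)
        _, p = windkessel_pressure(constant_waveform(q), self.WK_SUBJECT)
        expected = (0.00187 + 0.0355) * q
        assert p == pytest.approx(expected, rel=1e-12)

    def test_printed_subject_parameters_give_10_mmhg(self):
        q = l_min_to_mm3s(1.46 + 0.73)
        _, p = windkessel_pressure(constant_waveform(q), self.WK_SUBJECT)
        assert round(pa_to_mmhg(np.mean(p))) == 10

    def test_sinusoidal_mean_pressure_unchanged_by_capacitance(self):
        wf = FlowWaveform(
            3.2, np.arange(128) * 3.2 / 128,
            20_000.0 * (1 + 0.4 * np.cos(2 * np.pi * np.arange(128) / 128)),
        )
        t, p = windkessel_pressure(wf, self.WK_SUBJECT, dt=0.005, n_cycles=6)
        assert np.mean(p) == pytest.approx(
            (0.00187 + 0.0355) * wf.mean_flow(), rel=1e-3
        )

    def test_step_size_guard(self):
        with pytest.raises(InvalidParameterError):
            windkessel_pressure(constant_waveform(1000.0), self.WK_SUBJECT, dt=1.0)


class TestTuneWindkessel:
    def test_reproduces_printed_subject_resistances(self):
        # total flow from the reported group-mean RCIV+LCIV flows
        wk = tune_windkessel(l_min_to_mm3s(1.487 + 0.635), mmhg_to_pa(10.0), 0.05, 22.4)
        assert wk.r_proximal == pytest.approx(0.00187, rel=0.02)
        assert wk.r_distal == pytest.approx(0.0355, rel=0.02)

    def test_reproduces_printed_control_resistances(self):
        wk = tune_windkessel(l_min_to_mm3s(0.816 + 0.914), mmhg_to_pa(10.0), 0.05, 12.6)
        assert wk.r_proximal == pytest.approx(0.00237, rel=0.05)
        assert wk.r_distal == pytest.approx(0.0451, rel=0.05)

    def test_tuned_parameters_hit_target_pressure(self):
        q = l_min_to_mm3s(2.0)
        wk = tune_windkessel(q, mmhg_to_pa(10.0), 0.05, 20.0)
        wf = FlowWaveform(
            3.2, np.arange(64) * 3.2 / 64,
            q * (1 + 0.3 * np.cos(2 * np.pi * np.arange(64) / 64)),
        )
        _, p = windkessel_pressure(wf, wk)
        assert np.mean(p) == pytest.approx(mmhg_to_pa(10.0), rel=0.005)

    def test_resistance_inversely_proportional_to_flow(self):
        wk1 = tune_windkessel(1000.0, 1333.22, 0.05, 20.0)
        wk2 = tune_windkessel(2000.0, 1333.22, 0.05, 20.0)
        assert wk2.r_proximal == pytest.approx(wk1.r_proximal / 2, rel=1e-12)
        assert wk2.r_distal == pytest.approx(wk1.r_distal / 2, rel=1e-12)

    def test_invalid_target(self):
        with pytest.raises(InvalidParameterError):
            tune_windkessel(l_min_to_mm3s(1.0), 0.0)


class TestSimulatePatient:
    def test_symmetric_patient_has_equal_sides(self, phasic_newtonian_solution):
        _, sol, _ = phasic_newtonian_solution
        mean_l = sol.segments["LCIV"].wall_shear.mean()
        mean_r = sol.segments["RCIV"].wall_shear.mean()
        assert mean_l == pytest.approx(mean_r, rel=0.01)

    def test_stenosis_raises_throat_shear(self):
        base = subject_template(severity_range=(0.6, 0.6), noise_cv=0.0)
        none = subject_template(severity_range=(0.01, 0.01), noise_cv=0.0)
        p_sten = make_virtual_patient(base, 7)
        p_open = make_virtual_patient(none, 7)
        s_sten = simulate_patient(p_sten)
        s_open = simulate_patient(p_open)
        j = np.argmin(p_sten.segments["LCIV"].area_profile)
        assert (
            s_sten.segments["LCIV"].wall_shear[:, j].mean()
            > s_open.segments["LCIV"].wall_shear[:, j].mean()
        )

    def test_small_capacitance_limit_tracks_resistive_pressure(self):
        # with the RC time constant far below the respiratory period the
        # outlet pressure degenerates to pointwise R_total * Q(t)
        p = make_virtual_patient(control_template(noise_cv=0.0), 3)
        q = route_flows(p.inflows)["IVC"]
        wk = tune_windkessel(q.mean_flow(), mmhg_to_pa(10.0), 0.05, capacitance=0.05)
        t, pr = windkessel_pressure(q, wk, dt=0.001)
        expected = wk.r_total * q.at(t)
        assert pr == pytest.approx(expected, rel=0.005)

    def test_junction_conservation_every_step(self, phasic_newtonian_solution):
        _, sol, _ = phasic_newtonian_solution
        assert sol.segments["IVC"].flow == pytest.approx(
            sol.segments["RCIV"].flow + sol.segments["LCIV"].flow, rel=1e-9
        )

    def test_pressure_decreases_from_inlets_to_outlet(self):
        p = make_virtual_patient(subject_template(), 9)
        sol = simulate_patient(p)
        # along each segment, pressure must decrease in the flow direction
        ivc = sol.segments["IVC"].pressure
        assert np.all(np.diff(ivc, axis=1) <= 1e-9)  # z grows toward outlet
        for civ in ("RCIV", "LCIV"):
            seg = sol.segments[civ].pressure
            assert np.all(np.diff(seg, axis=1) >= -1e-9)  # z grows upstream
            # junction continuity: CIV start = IVC start
            assert seg[:, 0] == pytest.approx(ivc[:, 0], rel=1e-12)
        assert np.min(sol.segments["LEIV"].pressure) >= np.min(ivc) - 1e-9

    def test_quasi_steady_velocity_consistency(self, phasic_newtonian_solution):
        _, sol, _ = phasic_newtonian_solution
        seg = sol.segments["RCIV"]
        assert seg.mean_velocity.mean(axis=0) == pytest.approx(
            seg.flow.mean() / seg.area, rel=1e-9
        )

    def test_newtonian_profiles_match_closed_form(self, steady_newtonian_solution):
        _, sol, _ = steady_newtonian_solution
        seg = sol.segments["RCIV"]
        expected = poiseuille_wall_shear(seg.flow[0], seg.radius[0])
        assert seg.wall_shear[0, 0] == pytest.approx(expected, rel=1e-6)
        prof = sol.radial_profile("RCIV", 0.0, 0)
        r, radius = prof.radius_grid, seg.radius[0]
        u_exact = 2 * seg.flow[0] / (np.pi * radius**2) * (1 - (r / radius) ** 2)
        assert prof.axial_velocity == pytest.approx(u_exact, rel=1e-6, abs=1e-6 * u_exact[0])
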