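"""Control-volume and shear-metric tests.

The closed-form oracle used repeatedly: steady Newtonian Poiseuille flow in
a uniform cylinder has γ̇(r) = γ̇_w·r/R, so the annular-volume CDF of the
shear rate is F(γ) = (γ/γ̇_w)² and the volume-weighted mean, Q1 and Q3 are
(2/3, 0.5, √3/2)·γ̇_w.
"""

import numpy as np
import pytest

from conftest import poiseuille_wall_shear
from iliacshear.cohort import StenosisSpec, VesselSegment, make_virtual_patient, subject_template
from iliacshear.errors import AmbiguousStenosisError, CoverageError, GeometryError
from iliacshear.hemodynamics import SolverOptions, simulate_patient
from iliacshear.metrics import (
    ControlVolume,
    control_volume_for_control_group,
    cv_shear_metrics,
    detect_stenosis_extent,
    matched_contralateral_cv,
    patient_metrics,
    ratio_series,
    weighted_quantile,
)


def uniform_segment(name="LCIV", area=100.0, length=60.0, n=61, origin=0.0):
    return VesselSegment(name, np.linspace(0, length, n), np.full(n, area), origin)


class TestDetectStenosisExtent:
    def test_constant_area_gives_empty_extent(self):
        assert detect_stenosis_extent(uniform_segment()) is None

    def test_printed_rule_on_discrete_profile(self):
        z = np.arange(7.0) * 10.0
        area = np.array([100.0, 100.0, 80.0, 60.0, 80.0, 100.0, 100.0])
        cv = detect_stenosis_extent(VesselSegment("LCIV", z, area), flank_window=10.0)
        assert cv.z_start == 20.0 and cv.z_end == 40.0

    def test_cosine_bump_bounds_match_analytic_roots(self):
        # pure cosine bump severity 0.5 on A0: A = 0.9 A0 at
        # d = (L/2π) arccos(2*0.1/0.5 − 1) each side of the centre
        a0, length, zc, sev = 130.0, 30.0, 30.0, 0.5
        spec = StenosisSpec(sev, zc, length)
        z = np.linspace(0, 60, 241)
        seg = VesselSegment("LCIV", z, a0 * spec.area_factor(z))
        cv = detect_stenosis_extent(seg)
        d = length / (2 * np.pi) * np.arccos(2 * 0.1 / sev - 1.0)
        dz = z[1] - z[0]
        assert cv.z_start == pytest.approx(zc - d, abs=dz)
        assert cv.z_end == pytest.approx(zc + d, abs=dz)

    def test_two_disjoint_dips_are_ambiguous(self):
        z = np.arange(11.0) * 6.0
        area = np.full(11, 100.0)
        area[2] = area[8] = 50.0
        with pytest.raises(AmbiguousStenosisError) as err:
            detect_stenosis_extent(VesselSegment("LCIV", z, area))
        assert len(err.value.runs) == 2

    def test_control_template_patients_always_empty(self):
        from iliacshear.cohort import control_template, make_cohort

        for p in make_cohort(control_template(), 4, 123):
            assert detect_stenosis_extent(p.segments["LCIV"]) is None


class TestMatchedContralateralCV:
    def test_equal_vessels_equal_bounds(self):
        lciv_cv = ControlVolume("LCIV", 20.0, 40.0, 2000.0, 20.0)
        rciv = uniform_segment("RCIV", area=100.0)
        cv = matched_contralateral_cv(lciv_cv, rciv)
        assert cv.z_start == 20.0
        assert cv.z_end == pytest.approx(40.0, abs=1e-6)
        assert cv.volume == pytest.approx(2000.0, rel=1e-3)

    def test_double_area_halves_length(self):
        lciv_cv = ControlVolume("LCIV", 20.0, 40.0, 2000.0, 20.0)
        cv = matched_contralateral_cv(lciv_cv, uniform_segment("RCIV", area=200.0))
        assert cv.z_end - cv.z_start == pytest.approx(10.0, abs=1e-6)

    def test_tapered_vessel_against_analytic_inversion(self):
        # A(z) = 100 + z: cumulative volume V(z) = 100 z + z²/2 from z=10
        z = np.linspace(0, 60, 601)
        rciv = VesselSegment("RCIV", z, 100.0 + z)
        target = 1500.0
        lciv_cv = ControlVolume("LCIV", 10.0, 30.0, target, 10.0)
        cv = matched_contralateral_cv(lciv_cv, rciv)
        # solve 100(z−10) + (z²−100)/2 = 1500 exactly
        roots = np.roots([0.5, 100.0, -(target + 1000.0 + 50.0)])
        z_exact = roots[roots > 0][0]
        assert cv.z_end == pytest.approx(z_exact, rel=1e-3)

    def test_too_short_vessel_reports_shortfall(self):
        lciv_cv = ControlVolume("LCIV", 50.0, 58.0, 5000.0, 50.0)
        with pytest.raises(GeometryError, match="shortfall"):
            matched_contralateral_cv(lciv_cv, uniform_segment("RCIV", area=100.0))


class TestControlGroupCV:
    def test_single_subject_cv_passthrough(self):
        sub = ControlVolume("LCIV", 15.0, 35.0, 1800.0, 15.0)
        cv = control_volume_for_control_group([sub], uniform_segment("LCIV", area=90.0))
        assert cv.start_distance == 15.0
        assert cv.volume == pytest.approx(1800.0, rel=1e-3)

    def test_volume_is_mean_of_subjects(self):
        subs = [
            ControlVolume("LCIV", 10.0, 20.0, 100.0, 10.0),
            ControlVolume("LCIV", 20.0, 30.0, 300.0, 20.0),
        ]
        cv = control_volume_for_control_group(subs, uniform_segment("LCIV", area=100.0))
        assert cv.volume == pytest.approx(200.0, rel=1e-3)
        assert cv.start_distance == 15.0

    def test_empty_subject_list_rejected(self):
        with pytest.raises(GeometryError):
            control_volume_for_control_group([], uniform_segment())


class TestWeightedQuantile:
    def test_matches_hazen_convention_with_equal_weights(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        w = np.ones_like(x)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert weighted_quantile(x, w, q) == pytest.approx(
                np.quantile(x, q, method="hazen"), rel=1e-12
            )

    def test_monotone_in_q_and_clamped_to_extremes(self):
        rng = np.random.default_rng(3)
        x, w = rng.normal(size=40), rng.uniform(0.1, 1.0, size=40)
        qs = np.linspace(0.0, 1.0, 21)
        vals = weighted_quantile(x, w, qs)
        assert np.all(np.diff(vals) >= 0)
        assert vals[0] == x.min() and vals[-1] == x.max()

    def test_continuous_cdf_oracle(self):
        # linear values with weights proportional to the value sample the
        # CDF F(v) = (v/vmax)**2, so the q-quantile tends to sqrt(q)*vmax
        v = np.linspace(0.0, 1.0, 20_001)
        got = weighted_quantile(v, v, (0.25, 0.5, 0.75))
        assert got == pytest.approx(np.sqrt([0.25, 0.5, 0.75]), rel=1e-3)

    def test_ordering(self):
        rng = np.random.default_rng(2)
        x, w = rng.normal(size=50), rng.uniform(0.1, 1.0, size=50)
        q1, q2, q3 = weighted_quantile(x, w, (0.25, 0.5, 0.75))
        assert q1 <= q2 <= q3


class TestCVShearMetrics:
    def test_poiseuille_cylinder_closed_form(self, steady_newtonian_solution):
        _, sol, _ = steady_newtonian_solution
        seg = sol.segments["RCIV"]
        cv = ControlVolume(
            "RCIV", 10.0, 50.0, float(seg.area[0] * 40.0), 10.0
        )
        rec = cv_shear_metrics(sol, cv)
        gw = poiseuille_wall_shear(seg.flow[0], seg.radius[0])
        assert rec.mean_shear == pytest.approx(2.0 / 3.0 * gw, rel=0.01)
        assert rec.q1_shear == pytest.approx(0.5 * gw, rel=0.01)
        assert rec.q3_shear == pytest.approx(np.sqrt(3.0) / 2.0 * gw, rel=0.01)

    def test_steady_flow_mean_peak_equals_mean(self, steady_newtonian_solution):
        _, sol, _ = steady_newtonian_solution
        seg = sol.segments["RCIV"]
        cv = ControlVolume("RCIV", 10.0, 50.0, float(seg.area[0] * 40.0), 10.0)
        rec = cv_shear_metrics(sol, cv)
        assert rec.mean_peak_shear == pytest.approx(rec.mean_shear, rel=1e-12)

    def test_phasic_newtonian_peak_scales_with_phasicity(self, phasic_newtonian_solution):
        # Newtonian tube shear is linear in Q, so the cycle peak of the
        # spatial mean is (1 + phasicity) times its time mean.
        _, sol, _ = phasic_newtonian_solution
        seg = sol.segments["RCIV"]
        cv = ControlVolume("RCIV", 10.0, 50.0, float(seg.area[0] * 40.0), 10.0)
        rec = cv_shear_metrics(sol, cv)
        assert rec.mean_peak_shear / rec.mean_shear == pytest.approx(1.3, rel=0.01)

    def test_quartile_ordering_and_peak_dominance(self):
        p = make_virtual_patient(subject_template(), 17)
        sol = simulate_patient(p)
        cv = detect_stenosis_extent(p.segments["LCIV"])
        rec = cv_shear_metrics(sol, cv)
        assert rec.q1_shear <= rec.mean_shear <= rec.q3_shear
        assert rec.mean_peak_shear >= rec.mean_shear

    def test_cv_outside_stored_stations_rejected(self, steady_newtonian_solution):
        _, sol, _ = steady_newtonian_solution
        cv = ControlVolume("RCIV", 10.0, 90.0, 8000.0, 10.0)
        with pytest.raises(CoverageError):
            cv_shear_metrics(sol, cv)


class TestRatioSeries:
    def test_mirror_symmetric_patient_ratio_is_one(self, phasic_newtonian_solution):
        _, sol, _ = phasic_newtonian_solution
        area = sol.segments["RCIV"].area[0]
        cv_l = ControlVolume("LCIV", 15.0, 45.0, float(area * 30), 15.0)
        cv_r = ControlVolume("RCIV", 15.0, 45.0, float(area * 30), 15.0)
        _, ratio, mean_ratio = ratio_series(sol, cv_l, cv_r)
        assert ratio == pytest.approx(1.0, rel=1e-9)
        assert mean_ratio == pytest.approx(1.0, rel=1e-9)

    def test_newtonian_ratio_scales_linearly_with_left_flow(
        self, symmetric_template, newtonian
    ):
        from dataclasses import replace as dreplace

        k = 1.5
        tmpl = symmetric_template
        scaled = type(tmpl)(**{
            **tmpl.__dict__,
            "left_leg_flow": (tmpl.left_leg_flow[0] * k, tmpl.left_leg_flow[1] * k),
        })
        base = make_virtual_patient(tmpl, 5)
        high = make_virtual_patient(scaled, 5)
        options = SolverOptions(rheology=newtonian)
        area = base.segments["RCIV"].area_profile[0]
        cv_l = ControlVolume("LCIV", 15.0, 45.0, float(area * 30), 15.0)
        cv_r = ControlVolume("RCIV", 15.0, 45.0, float(area * 30), 15.0)
        _, _, r_base = ratio_series(simulate_patient(base, options), cv_l, cv_r)
        _, _, r_high = ratio_series(simulate_patient(high, options), cv_l, cv_r)
        assert r_high / r_base == pytest.approx(k, rel=1e-6)

    def test_subject_ratio_exceeds_one_and_grows_with_severity(self):
        ratios = []
        for s in (0.45, 0.75):
            tmpl = subject_template(severity_range=(s, s), noise_cv=0.0)
            p = make_virtual_patient(tmpl, 3)
            sol = simulate_patient(p)
            cv = detect_stenosis_extent(p.segments["LCIV"])
            rcv = matched_contralateral_cv(cv, p.segments["RCIV"])
            ratios.append(patient_metrics(sol, cv, rcv)["ratio_mean"])
        assert ratios[0] > 1.0
        assert ratios[1] > ratios[0]
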