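"""Calibration of a patient model against ultrasound-like measurements.

The boundary conditions of a patient-specific venous model are not known a
priori: inflow magnitudes, the outlet Windkessel, and the luminal areas
(imaging and ultrasound disagree because venous caliber tracks hydration
status) all need tuning.  The loop here reconciles them against the
measured mean velocity and area in each common iliac vein:

1. scale each leg's inlet waveforms so the simulated RCIV/LCIV mean flows
   match the measured ones (v·A of the ultrasound record) within 2%;
2. retune the Windkessel total resistance so the mean outlet pressure hits
   the 10 mmHg venous target;
3. blend the imaging-derived area toward the ultrasound area per vessel —
   A = w·A_ct + (1−w)·A_us with a single weight w per vessel, found by
   monotone bisection so the simulated slice velocity matches the measured
   velocity within 10%.

Convergence is declared only when all three criteria hold simultaneously
on a fresh simulation of the final state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import FlowWaveform, UltrasoundRecord, VesselSegment, VirtualPatient
from .errors import CoverageError, DomainError, InvalidParameterError
from .hemodynamics import (
    NetworkSolution,
    SolverOptions,
    WindkesselParams,
    simulate_patient,
    tune_windkessel,
)
from .units import mmhg_to_pa

__all__ = [
    "CalibrationTargets",
    "CalibrationResult",
    "blend_areas",
    "velocity_error",
    "slice_mean_velocity",
    "calibrate_patient",
    "apply_calibration",
]


@dataclass(frozen=True)
class CalibrationTargets:
    """Tolerances of the three calibration criteria."""

    flow_tolerance: float = 0.02
    velocity_tolerance: float = 0.10
    target_pressure: float = mmhg_to_pa(10.0)
    pressure_tolerance: float = 0.02

    def __post_init__(self) -> None:
        for name in ("flow_tolerance", "velocity_tolerance", "pressure_tolerance"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InvalidParameterError(f"{name} must be in (0, 1), got {v}")


@dataclass
class CalibrationResult:
    """Final calibrated state and the residuals recomputed from it."""

    area_blend_weights: dict
    inflow_scales: dict
    windkessel: WindkesselParams
    flow_errors: dict
    velocity_errors: dict
    pressure_error: float
    converged: bool
    iterations: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["windkessel"] = dataclasses.asdict(self.windkessel)
        return json.dumps(d, indent=2, sort_keys=True)


def blend_areas(ct_area: float, us_area: float, w: float) -> float:
    """Linear blend A = w·A_ct + (1−w)·A_us of the two area sources."""
    if ct_area <= 0 or us_area <= 0:
        raise DomainError("areas must be > 0")
    if not (0.0 <= w <= 1.0):
        raise DomainError(f"blend weight must be in [0, 1], got {w}")
    return w * ct_area + (1.0 - w) * us_area


def velocity_error(simulated_mean_velocity: float, measured: float) -> float:
    """Relative slice-velocity mismatch |v_sim − v_meas| / v_meas."""
    if measured <= 0:
        raise DomainError("measured velocity must be > 0")
    return abs(simulated_mean_velocity - measured) / measured


def slice_mean_velocity(solution: NetworkSolution, vessel: str, z: float) -> float:
    """Time-mean of Q(t)/A at the stored station nearest ``z`` (mm/s)."""
    seg = solution.segments.get(vessel)
    if seg is None:
        raise CoverageError(f"solution stores no segment {vessel!r}")
    if z < seg.z[0] - 1e-6 or z > seg.z[-1] + 1e-6:
        raise CoverageError(f"slice z={z} mm outside segment {vessel}")
    j = int(np.argmin(np.abs(seg.z - z)))
    return float(np.mean(seg.flow) / seg.area[j])


def _scaled_patient(
    patient: VirtualPatient,
    inflow_scales: dict,
    area_scales: dict,
    frozen_inlets: frozenset,
) -> VirtualPatient:
    """Working copy with per-side inflow scaling and per-vessel area scaling."""
    inflows = {}
    for name, wf in patient.inflows.items():
        side = "left" if name[0] == "L" else "right"
        s = 1.0 if name in frozen_inlets else inflow_scales[side]
        inflows[name] = FlowWaveform(wf.period, wf.times.copy(), wf.flows * s)
    segments = {}
    for name, seg in patient.segments.items():
        s = area_scales.get(name, 1.0)
        segments[name] = VesselSegment(
            name, seg.arclength_grid.copy(), seg.area_profile * s, seg.origin_distance
        )
    return VirtualPatient(
        id=patient.id, group=patient.group, segments=segments, inflows=inflows,
        us_records=patient.us_records, seed=patient.seed, period=patient.period,
    )


def _side_scale(
    patient: VirtualPatient,
    side: str,
    target_flow: float,
    frozen_inlets: frozenset,
) -> float:
    """Scale factor on the side's non-frozen inlets reaching ``target_flow``."""
    names = [n for n in patient.inflows if (n[0] == "L") == (side == "left")]
    frozen = sum(patient.inflows[n].mean_flow() for n in names if n in frozen_inlets)
    free = sum(patient.inflows[n].mean_flow() for n in names if n not in frozen_inlets)
    if free <= 0:
        return 1.0
    return max((target_flow - frozen) / free, 1e-6)


def calibrate_patient(
    patient: VirtualPatient,
    targets: CalibrationTargets = CalibrationTargets(),
    max_iterations: int = 20,
    options: SolverOptions = SolverOptions(),
    frozen_inlets=(),
    measured_flows: Optional[dict] = None,
) -> CalibrationResult:
    """Run the flows → pressure → areas fixed-point loop.

    Measured mean flow per vessel defaults to v·A of its ultrasound record;
    ``measured_flows`` overrides it per vessel (waveform-derived flow and
    spectral velocity can disagree in practice).  ``frozen_inlets`` names
    inlets whose waveforms are left untouched by the flow-scaling step
    (mirroring cases where one inlet was never tuned).  Returns a
    diagnostic result with ``converged=False`` — never raises — when the
    loop runs out of iterations or no admissible blend weight can
    reconcile the velocity.
    """
    if not {"RCIV", "LCIV"} <= set(patient.us_records):
        raise InvalidParameterError("calibration needs US records for RCIV and LCIV")
    frozen = frozenset(frozen_inlets)
    records: dict = patient.us_records
    q_meas = {
        v: (measured_flows or {}).get(v, records[v].mean_flow)
        for v in ("RCIV", "LCIV")
    }
    side_of = {"RCIV": "right", "LCIV": "left"}

    inflow_scales = {"right": 1.0, "left": 1.0}
    weights = {"RCIV": 1.0, "LCIV": 1.0}
    area_scales = {"RCIV": 1.0, "LCIV": 1.0}
    wk = options.windkessel

    def run(opts_wk: Optional[WindkesselParams]) -> NetworkSolution:
        work = _scaled_patient(patient, inflow_scales, area_scales, frozen)
        opts = dataclasses.replace(options, windkessel=opts_wk)
        return simulate_patient(work, opts)

    converged = False
    feasible = True
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        # -- 1. inflow scaling to measured CIV mean flows.  Routing is purely
        # conservative, so the simulated CIV mean flow equals the scaled sum
        # of its side's inlets and the required scale follows directly.
        for vessel in ("RCIV", "LCIV"):
            inflow_scales[side_of[vessel]] = _side_scale(
                patient, side_of[vessel], q_meas[vessel], frozen
            )
        # -- 2. Windkessel retune to the target mean pressure
        total = q_meas["RCIV"] + q_meas["LCIV"]
        wk = tune_windkessel(
            total, targets.target_pressure, options.proximal_fraction, options.capacitance
        )
        # -- 3. area blend weight per vessel (monotone bisection on w)
        feasible = True
        for vessel, rec in records.items():
            if vessel not in ("RCIV", "LCIV"):
                continue
            ct_area = float(patient.segments[vessel].area_at(rec.slice_position))
            w, ok = _solve_blend_weight(
                ct_area, rec, targets.velocity_tolerance, q_meas[vessel]
            )
            weights[vessel] = w
            area_scales[vessel] = blend_areas(ct_area, rec.mean_area, w) / ct_area
            feasible = feasible and ok

        # -- convergence check on a fresh simulation of the final state
        sol = run(wk)
        flow_errors, vel_errors = {}, {}
        for vessel, rec in records.items():
            if vessel not in ("RCIV", "LCIV"):
                continue
            q_sim = float(np.mean(sol.segments[vessel].flow))
            flow_errors[vessel] = abs(q_sim - q_meas[vessel]) / q_meas[vessel]
            v_sim = slice_mean_velocity(sol, vessel, rec.slice_position)
            vel_errors[vessel] = velocity_error(v_sim, rec.mean_velocity)
        p_mean = float(np.mean(sol.outlet_pressure))
        p_err = abs(p_mean - targets.target_pressure) / targets.target_pressure
        if (
            feasible
            and all(e <= targets.flow_tolerance for e in flow_errors.values())
            and all(e <= targets.velocity_tolerance for e in vel_errors.values())
            and p_err <= targets.pressure_tolerance
        ):
            converged = True
            break

    return CalibrationResult(
        area_blend_weights=dict(weights),
        inflow_scales=dict(inflow_scales),
        windkessel=wk,
        flow_errors=flow_errors,
        velocity_errors=vel_errors,
        pressure_error=p_err,
        converged=converged,
        iterations=iterations,
    )


def _solve_blend_weight(ct_area: float, rec: UltrasoundRecord, tol: float, qbar: float):
    """Bisection on w ∈ [0, 1] for |Q̄/A(w) − v_meas|/v_meas <= tol.

    The slice velocity v(w) = Q̄_meas/A(w) is monotone in w (A is linear in
    w), so plain bisection on the signed residual suffices.  Returns
    ``(w, feasible)``; infeasible targets get the best endpoint.
    """

    def resid(w: float) -> float:
        return qbar / blend_areas(ct_area, rec.mean_area, w) - rec.mean_velocity

    r0, r1 = resid(0.0), resid(1.0)
    if abs(r0) <= tol * rec.mean_velocity:
        return 0.0, True
    if r0 * r1 > 0:  # no sign change: target velocity outside [v(0), v(1)]
        best = 0.0 if abs(r0) <= abs(r1) else 1.0
        return best, abs(resid(best)) <= tol * rec.mean_velocity
    lo, hi = 0.0, 1.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if resid(lo) * resid(mid) <= 0:
            hi = mid
        else:
            lo = mid
    w = 0.5 * (lo + hi)
    return w, abs(resid(w)) <= tol * rec.mean_velocity


def apply_calibration(patient: VirtualPatient, result: CalibrationResult) -> VirtualPatient:
    """Patient with the calibrated inflow scales and blended areas applied."""
    area_scales = {}
    for vessel, w in result.area_blend_weights.items():
        rec = patient.us_records[vessel]
        ct_area = float(patient.segments[vessel].area_at(rec.slice_position))
        area_scales[vessel] = blend_areas(ct_area, rec.mean_area, w) / ct_area
    return _scaled_patient(patient, result.inflow_scales, area_scales, frozenset())
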