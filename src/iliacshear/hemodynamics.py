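"""Reduced-order venous network solver.

The three-dimensional unsteady problem is replaced by a quasi-steady,
fully developed, axisymmetric (generalized-Poiseuille) model evaluated
per arclength station and per time sample — defensible at venous Womersley
numbers, where the flow tracks the respiratory driver almost statically.
The construction:

* In a straight tube of radius R carrying flow Q, momentum balance gives a
  linear stress profile τ(r) = G·r/2 with G = −dp/dz.  For a
  generalized-Newtonian fluid the local shear rate is γ̇(r) = τ⁻¹(τ(r)),
  the inverse of the monotone stress law, and the velocity is
  u(r) = ∫_r^R γ̇(s) ds (no-slip at the wall).  G is found so the profile
  integrates to the prescribed Q.
* Flows are routed through the fixed bilateral-iliac topology by mass
  conservation (inlets are prescribed, junctions sum).
* The outlet carries a three-element (RCR) Windkessel whose total
  resistance is tuned so the mean IVC pressure hits a 10 mmHg target.

For bulk evaluation the wall stress is obtained from a precomputed
Rabinowitsch tube law: with I(τ_w) = ∫₀^{τ_w} s²γ̇(s) ds, integrating the
profile by parts gives Q = πR³·I(τ_w)/τ_w³, so the single monotone scalar
function J(τ_w) = I(τ_w)/τ_w³ maps Q/(πR³) to the wall stress for any
radius.  J and its inverse are tabulated once per rheology with cumulative
Simpson quadrature on a dense logarithmic grid and interpolated with
monotone cubics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_simpson, simpson
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .cohort import INLETS, FlowWaveform, VirtualPatient
from .errors import (
    ConfigurationError,
    DomainError,
    InvalidParameterError,
    SolverError,
)
from .rheology import BLOOD, RheologyParams, shear_stress
from .units import mmhg_to_pa

__all__ = [
    "WindkesselParams",
    "RadialProfile",
    "SegmentSolution",
    "NetworkSolution",
    "SolverOptions",
    "invert_stress",
    "TubeLaw",
    "solve_generalized_poiseuille",
    "route_flows",
    "windkessel_pressure",
    "tune_windkessel",
    "simulate_patient",
    "export_solution",
]


def invert_stress(tau, params: RheologyParams):
    """Invert τ = μ(γ̇)·γ̇ for γ̇ >= 0 (scalar or array), 1/s.

    Safeguarded bisection on the bracket [τ/μ0, τ/μ∞] (valid because
    μ∞ <= μ(γ̇) <= μ0) run to a relative width below 1e-10.  The stress law
    is strictly monotone — enforced at parameter construction — so the root
    is unique.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0) or not np.all(np.isfinite(tau_arr)):
        raise DomainError("shear stress must be finite and >= 0")
    lo = tau_arr / params.mu_0
    hi = tau_arr / params.mu_inf
    # Bracket width shrinks by 2^-60; starting ratio mu_0/mu_inf is modest,
    # so the final relative width is far below 1e-10.
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = shear_stress(mid, params, _validate=False) < tau_arr
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    return out if out.ndim else float(out)


class TubeLaw:
    """Precomputed Q ↔ wall-stress relation for fully developed tube flow.

    Tabulates I(τ) = ∫₀^τ s²γ̇(s) ds on a 4096-node logarithmic grid
    (cumulative Simpson in log-space, analytic Newtonian tail below the
    grid) and interpolates J(τ) = I(τ)/τ³ and its inverse with monotone
    log-log cubics.
    """

    TAU_MIN = 1e-7
    TAU_MAX = 1e7
    N_NODES = 4096

    def __init__(self, params: RheologyParams):
        self.params = params
        x = np.linspace(np.log(self.TAU_MIN), np.log(self.TAU_MAX), self.N_NODES)
        tau = np.exp(x)
        gamma = invert_stress(tau, params)
        # I(tau) = int s^2 gamma ds = int s^3 gamma d(ln s); seed the lowest
        # node with the Newtonian-plateau closed form tau^4/(4 mu_0).
        integrand = tau**3 * gamma
        i_tab = cumulative_simpson(integrand, x=x, initial=0.0)
        i_tab += tau[0] ** 4 / (4.0 * params.mu_0)
        j_tab = i_tab / tau**3
        if np.any(np.diff(j_tab) <= 0):  # pragma: no cover - guaranteed by monotone stress
            raise SolverError("tube-law table is not monotone")
        self._log_j = PchipInterpolator(x, np.log(j_tab))
        self._inv = PchipInterpolator(np.log(j_tab), x)
        self._j_lo, self._j_hi = j_tab[0], j_tab[-1]

    def wall_stress(self, flow, radius):
        """Wall shear stress τ_w (Pa) for flow(s) Q (mm^3/s) in radius R (mm).

        Broadcasts ``flow`` against ``radius``; Q = 0 maps to τ_w = 0.
        Below the tabulated range the Newtonian zero-shear closed form
        τ_w = 4μ0·Q/(πR³) applies.
        """
        q = np.asarray(flow, dtype=float)
        r = np.asarray(radius, dtype=float)
        if np.any(q < 0):
            raise DomainError("tube-law flow must be >= 0")
        j = q / (np.pi * r**3)
        out = np.zeros(np.broadcast_shapes(q.shape, r.shape))
        j = np.broadcast_to(j, out.shape)
        pos = j > 0
        small = pos & (j <= self._j_lo)
        out[small] = 4.0 * self.params.mu_0 * j[small]
        mid = pos & ~small
        if np.any(j > self._j_hi):
            raise SolverError("flow outside tabulated tube-law range")
        out[mid] = np.exp(self._inv(np.log(j[mid])))
        return out if out.ndim else float(out)

    def wall_shear_rate(self, flow, radius):
        """Wall shear rate γ̇_w = τ⁻¹(τ_w), 1/s."""
        return invert_stress(self.wall_stress(flow, radius), self.params)


@dataclass
class RadialProfile:
    """Axisymmetric station profile: u(r), γ̇(r), the axial pressure
    gradient G = −dp/dz and the integrated flow."""

    radius_grid: np.ndarray
    axial_velocity: np.ndarray
    shear_rate: np.ndarray
    pressure_gradient: float
    flow: float

    @property
    def wall_shear_rate(self) -> float:
        return float(self.shear_rate[-1])

    def integrate_flow(self) -> float:
        """Recompute Q = 2π ∫ r·u dr from the stored profile."""
        return float(2.0 * np.pi * simpson(self.radius_grid * self.axial_velocity,
                                           x=self.radius_grid))


def solve_generalized_poiseuille(
    flow: float,
    radius: float,
    params: RheologyParams = BLOOD,
    n_radial: int = 128,
) -> RadialProfile:
    """Fully developed axisymmetric profile carrying a prescribed flow.

    Finds the pressure gradient G such that the profile with τ(r) = G·r/2,
    γ̇(r) = τ⁻¹(τ(r)) and u(r) = ∫_r^R γ̇ integrates (Simpson) to ``flow``,
    by bracketing + Brent iteration on G to 1e-10 relative.  The Newtonian
    bracket [8μ∞Q/(πR⁴), 8μ0Q/(πR⁴)] always contains the root because the
    apparent viscosity lies between the plateaus.
    """
    if flow < 0 or radius <= 0:
        raise InvalidParameterError("need flow >= 0 and radius > 0")
    if n_radial < 32:
        raise InvalidParameterError("n_radial must be >= 32")
    r = np.linspace(0.0, radius, n_radial)
    if flow == 0.0:
        zero = np.zeros(n_radial)
        return RadialProfile(r, zero.copy(), zero.copy(), 0.0, 0.0)

    def q_of(g: float) -> float:
        gamma = invert_stress(0.5 * g * r, params)
        return float(np.pi * simpson(r * r * gamma, x=r))

    g_lo = 8.0 * params.mu_inf * flow / (np.pi * radius**4) * 0.5
    g_hi = 8.0 * params.mu_0 * flow / (np.pi * radius**4) * 2.0
    f_lo, f_hi = q_of(g_lo) - flow, q_of(g_hi) - flow
    if f_lo > 0 or f_hi < 0:
        raise SolverError(
            f"failed to bracket pressure gradient for Q={flow} mm^3/s, R={radius} mm: "
            f"Q({g_lo:.3e})={f_lo + flow:.6e}, Q({g_hi:.3e})={f_hi + flow:.6e}"
        )
    g_star = brentq(lambda g: q_of(g) - flow, g_lo, g_hi, rtol=1e-12, xtol=1e-300)
    gamma = invert_stress(0.5 * g_star * r, params)
    cum = cumulative_simpson(gamma, x=r, initial=0.0)
    u = cum[-1] - cum  # u(r) = int_r^R gamma
    return RadialProfile(r, u, gamma, float(g_star), float(flow))


def route_flows(inflows: dict, n_samples: Optional[int] = None) -> dict:
    """Propagate the four inlet waveforms through the fixed topology.

    Returns waveforms for all seven segments on a shared uniform time grid:
    RCIV = REIV + RIIV, LCIV = LEIV + LIIV, IVC = RCIV + LCIV, pointwise in
    time.  All inlets must share one period (to 1e-9 relative).
    """
    missing = [v for v in INLETS if v not in inflows]
    if missing:
        raise ConfigurationError(f"missing inlet waveforms: {missing}")
    periods = [inflows[v].period for v in INLETS]
    t0 = periods[0]
    if any(abs(p - t0) > 1e-9 * t0 for p in periods):
        raise ConfigurationError(f"inlet periods differ: {periods}")
    n = n_samples or max(len(inflows[v].times) for v in INLETS)
    out = {v: inflows[v].resample(n) for v in INLETS}
    times = out["REIV"].times

    def merged(a: str, b: str) -> FlowWaveform:
        return FlowWaveform(t0, times.copy(), out[a].flows + out[b].flows)

    out["RCIV"] = merged("REIV", "RIIV")
    out["LCIV"] = merged("LEIV", "LIIV")
    out["IVC"] = FlowWaveform(t0, times.copy(), out["RCIV"].flows + out["LCIV"].flows)
    return out


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element (RCR) lumped outflow model, mm-g-s units:
    proximal resistance (Pa·s/mm³), capacitance (mm³/Pa), distal resistance
    (Pa·s/mm³), plus the distal reference pressure (Pa, gauge)."""

    r_proximal: float
    capacitance: float
    r_distal: float
    reference_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.r_proximal <= 0 or self.r_distal <= 0 or self.capacitance <= 0:
            raise InvalidParameterError("Windkessel resistances and capacitance must be > 0")

    @property
    def r_total(self) -> float:
        return self.r_proximal + self.r_distal


def windkessel_pressure(
    outlet_flow: FlowWaveform,
    wk: WindkesselParams,
    dt: float = 0.01,
    n_cycles: int = 4,
):
    """Integrate the RCR outlet over ``n_cycles`` periods and return the
    last full cycle.

    State equation C·dP_c/dt = Q − (P_c − P_ref)/R_d with outlet pressure
    P = R_p·Q + P_c, advanced with classical RK4.  The state starts at its
    cycle-mean fixed point P_ref + R_d·Q̄ so the discarded first cycle
    absorbs any residual transient.  Returns ``(times, pressure)`` with
    times rebased to [0, T) of the final cycle.
    """
    period = outlet_flow.period
    if dt > period / 50:
        raise InvalidParameterError(f"dt must be <= period/50 = {period / 50:.4g} s")
    if n_cycles < 2:
        raise InvalidParameterError("n_cycles must be >= 2")
    n_per = int(round(period / dt))
    dt = period / n_per  # snap so cycles tile exactly
    n_total = n_per * n_cycles
    t = np.arange(n_total + 1) * dt
    q = outlet_flow.at(t)

    def rhs(pc: float, qt: float) -> float:
        return (qt - (pc - wk.reference_pressure) / wk.r_distal) / wk.capacitance

    pc = np.empty(n_total + 1)
    pc[0] = wk.reference_pressure + wk.r_distal * outlet_flow.mean_flow()
    q_mid = outlet_flow.at(t[:-1] + 0.5 * dt)
    for k in range(n_total):
        y = pc[k]
        k1 = rhs(y, q[k])
        k2 = rhs(y + 0.5 * dt * k1, q_mid[k])
        k3 = rhs(y + 0.5 * dt * k2, q_mid[k])
        k4 = rhs(y + dt * k3, q[k + 1])
        pc[k + 1] = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(pc[k + 1]):
            raise SolverError(f"Windkessel integration diverged at t={t[k + 1]:.4f} s; reduce dt")
    p = wk.r_proximal * q + pc
    sl = slice(n_total - n_per, n_total)
    return t[sl] - t[sl.start], p[sl]


def tune_windkessel(
    mean_flow: float,
    target_mean_pressure: float,
    proximal_fraction: float = 0.05,
    capacitance: float = 20.0,
    reference_pressure: float = 0.0,
) -> WindkesselParams:
    """Size the RCR so the cycle-mean outlet pressure hits the target.

    In periodic state the capacitor carries no mean current, so the mean
    pressure is P_ref + (R_p + R_d)·Q̄ exactly; the total resistance is
    therefore (target − P_ref)/Q̄, split by ``proximal_fraction``.
    """
    if mean_flow <= 0:
        raise InvalidParameterError("mean_flow must be > 0")
    if not (0 < proximal_fraction < 1):
        raise InvalidParameterError("proximal_fraction must be in (0, 1)")
    if target_mean_pressure <= reference_pressure:
        raise InvalidParameterError(
            f"target pressure {target_mean_pressure} must exceed the reference "
            f"{reference_pressure}"
        )
    r_total = (target_mean_pressure - reference_pressure) / mean_flow
    return WindkesselParams(
        r_proximal=proximal_fraction * r_total,
        capacitance=capacitance,
        r_distal=(1.0 - proximal_fraction) * r_total,
        reference_pressure=reference_pressure,
    )


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings for :func:`simulate_patient`.

    station_spacing : mm between stored arclength stations (default 1).
    n_time : time samples per respiratory cycle for the quasi-steady solves.
    n_radial : radial nodes of reconstructed profiles.
    dt / n_cycles : Windkessel integration step and cycle count.
    windkessel : explicit RCR parameters; None tunes to ``target_pressure``.
    """

    rheology: RheologyParams = BLOOD
    station_spacing: float = 1.0
    n_time: int = 64
    n_radial: int = 128
    dt: float = 0.01
    n_cycles: int = 4
    windkessel: Optional[WindkesselParams] = None
    target_pressure: float = mmhg_to_pa(10.0)
    proximal_fraction: float = 0.05
    capacitance: float = 20.0


@dataclass
class SegmentSolution:
    """Per-segment fields on (time, station) grids.  Flow is uniform along
    a rigid segment, so ``flow`` is a time series."""

    name: str
    z: np.ndarray
    area: np.ndarray
    flow: np.ndarray
    wall_stress: np.ndarray  # (n_time, n_z), Pa
    wall_shear: np.ndarray  # (n_time, n_z), 1/s
    pressure: np.ndarray  # (n_time, n_z), Pa
    origin_distance: float

    @property
    def radius(self) -> np.ndarray:
        return np.sqrt(self.area / np.pi)

    @property
    def mean_velocity(self) -> np.ndarray:
        """Q(t)/A(z), shape (n_time, n_z), mm/s."""
        return self.flow[:, None] / self.area[None, :]


@dataclass
class NetworkSolution:
    """Quasi-steady network solution over one respiratory cycle."""

    times: np.ndarray
    period: float
    segments: dict
    windkessel: WindkesselParams
    outlet_pressure: np.ndarray
    tube_law: TubeLaw
    options: SolverOptions

    def radial_profile(self, segment: str, z: float, time_index: int) -> RadialProfile:
        """Reconstruct the full radial profile at the station nearest ``z``."""
        seg = self.segments[segment]
        j = int(np.argmin(np.abs(seg.z - z)))
        return solve_generalized_poiseuille(
            float(seg.flow[time_index]),
            float(seg.radius[j]),
            self.tube_law.params,
            self.options.n_radial,
        )

    def shear_profiles(self, segment: str, z_values: np.ndarray):
        """Vectorized γ̇(t, z, r) for arbitrary arclength positions.

        Returns ``(radius, gamma)`` with radius (n_z, n_r) and gamma
        (n_time, n_z, n_r); the linear stress profile τ = τ_w·r/R is
        inverted through the rheology at every node.
        """
        seg = self.segments[segment]
        z_values = np.atleast_1d(np.asarray(z_values, dtype=float))
        area = np.interp(z_values, seg.z, seg.area)
        radius = np.sqrt(area / np.pi)
        tau_w = self.tube_law.wall_stress(seg.flow[:, None], radius[None, :])
        frac = np.linspace(0.0, 1.0, self.options.n_radial)
        tau = tau_w[:, :, None] * frac[None, None, :]
        gamma = invert_stress(tau, self.tube_law.params)
        r = radius[:, None] * frac[None, :]
        return r, gamma


def simulate_patient(patient: VirtualPatient, options: SolverOptions = SolverOptions()) -> NetworkSolution:
    """Run the reduced-order model for one patient.

    Routes inlet waveforms by conservation, tunes (or applies) the outlet
    Windkessel, then evaluates the generalized-Poiseuille tube law at every
    stored station and time sample.  Pressure is assembled from the outlet
    upward by accumulating the local gradient G = 2τ_w/R along each path.
    """
    flows = route_flows(patient.inflows, n_samples=options.n_time)
    times = flows["IVC"].times
    law = _tube_law_cache(options.rheology)

    wk = options.windkessel
    if wk is None:
        wk = tune_windkessel(
            flows["IVC"].mean_flow(),
            options.target_pressure,
            options.proximal_fraction,
            options.capacitance,
        )
    t_wk, p_wk = windkessel_pressure(flows["IVC"], wk, options.dt, options.n_cycles)
    outlet_pressure = np.interp(times, t_wk, p_wk, period=flows["IVC"].period)

    segments = {}
    for name, seg in patient.segments.items():
        n_z = max(int(round(seg.length / options.station_spacing)) + 1, 3)
        z = np.linspace(seg.arclength_grid[0], seg.arclength_grid[-1], n_z)
        area = seg.area_at(z)
        radius = np.sqrt(area / np.pi)
        q = flows[name].flows
        tau_w = law.wall_stress(q[:, None], radius[None, :])
        wall_shear = invert_stress(tau_w, options.rheology)
        segments[name] = SegmentSolution(
            name=name, z=z, area=area, flow=q, wall_stress=tau_w,
            wall_shear=wall_shear, pressure=np.zeros_like(tau_w),
            origin_distance=seg.origin_distance,
        )

    # Pressure accumulation.  Drainage runs inlets -> CIVs -> IVC -> outlet;
    # pressure rises upstream by the local gradient G = 2 tau_w / R.
    def _accumulate(seg: SegmentSolution, p_downstream: np.ndarray, downstream_end: str) -> None:
        g = 2.0 * seg.wall_stress / seg.radius[None, :]
        dz = np.diff(seg.z)
        mid = 0.5 * (g[:, 1:] + g[:, :-1]) * dz[None, :]
        if downstream_end == "last":
            drop = np.concatenate(
                [np.cumsum(mid[:, ::-1], axis=1)[:, ::-1], np.zeros((g.shape[0], 1))], axis=1
            )
        else:
            drop = np.concatenate([np.zeros((g.shape[0], 1)), np.cumsum(mid, axis=1)], axis=1)
        seg.pressure[:] = p_downstream[:, None] + drop

    ivc = segments["IVC"]
    _accumulate(ivc, outlet_pressure, "last")  # z = L is the Windkessel outlet
    junction_p = ivc.pressure[:, 0]
    for civ in ("RCIV", "LCIV"):
        _accumulate(segments[civ], junction_p, "first")  # z = 0 at the bifurcation
    for inlet in INLETS:
        parent = segments["RCIV" if inlet[0] == "R" else "LCIV"]
        _accumulate(segments[inlet], parent.pressure[:, -1], "first")

    return NetworkSolution(
        times=times, period=flows["IVC"].period, segments=segments,
        windkessel=wk, outlet_pressure=outlet_pressure, tube_law=law,
        options=options,
    )


_LAW_CACHE: dict = {}


def _tube_law_cache(params: RheologyParams) -> TubeLaw:
    key = (params.mu_inf, params.mu_0, params.n, params.a, params.lam)
    if key not in _LAW_CACHE:
        _LAW_CACHE[key] = TubeLaw(params)
    return _LAW_CACHE[key]


def export_solution(solution: NetworkSolution, directory) -> None:
    """Write per-segment CSVs (t_s, z_mm, q_mm3_s, p_pa, wall_shear_1_s,
    mean_velocity_mm_s) plus a JSON run manifest."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, seg in solution.segments.items():
        with open(directory / f"segment_{name}.csv", "w") as fh:
            fh.write("t_s,z_mm,q_mm3_s,p_pa,wall_shear_1_s,mean_velocity_mm_s\n")
            v = seg.mean_velocity
            for i, t in enumerate(solution.times):
                for j, z in enumerate(seg.z):
                    fh.write(
                        f"{t:.5f},{z:.3f},{seg.flow[i]:.6f},{seg.pressure[i, j]:.6f},"
                        f"{seg.wall_shear[i, j]:.6f},{v[i, j]:.6f}\n"
                    )
    manifest = {
        "period_s": solution.period,
        "windkessel": {
            "r_proximal": solution.windkessel.r_proximal,
            "capacitance": solution.windkessel.capacitance,
            "r_distal": solution.windkessel.r_distal,
            "reference_pressure": solution.windkessel.reference_pressure,
        },
        "options": {
            "station_spacing": solution.options.station_spacing,
            "n_time": solution.options.n_time,
            "n_radial": solution.options.n_radial,
            "dt": solution.options.dt,
            "n_cycles": solution.options.n_cycles,
        },
    }
    (directory / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
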