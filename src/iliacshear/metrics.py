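"""Control-volume shear-rate metrics.

Metrics are extracted over control volumes rather than single slices so
that one number summarizes a whole region of interest:

* The stenotic LCIV control volume is the contiguous region whose area
  falls below 90% of the uncompressed proximal and distal reference areas
  (the smaller of the two flank references — the conservative reading).
* The contralateral RCIV control volume starts at the same distance from
  the common iliac bifurcation and is solved to enclose an identical
  volume, making the right side a fair internal control.
* Control-group patients, which have no stenosis, inherit the average
  size and position of the case-group control volumes.

Within a control volume, shear-rate samples are taken on the reconstructed
radial profiles of every station and weighted by annular volume
(2πr·Δr·Δz).  Reported metrics: volume-weighted mean, first and third
weighted quartiles (time-averaged over the respiratory cycle), the cycle
peak of the volume-mean ("mean peak"), and the LCIV/RCIV mean-shear ratio,
the patient-level quantity that uses the right side as an internal control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import VesselSegment
from .errors import AmbiguousStenosisError, CoverageError, DomainError, GeometryError
from .hemodynamics import NetworkSolution
from .units import mm3s_to_l_min

__all__ = [
    "ControlVolume",
    "ShearDistribution",
    "MetricsRecord",
    "detect_stenosis_extent",
    "matched_contralateral_cv",
    "control_volume_for_control_group",
    "cv_shear_metrics",
    "ratio_series",
    "weighted_quantile",
    "patient_metrics",
]


@dataclass(frozen=True)
class ControlVolume:
    """Axial evaluation region of one vessel.

    ``volume`` is ∫A dz over [z_start, z_end]; ``start_distance`` locates
    z_start relative to the common iliac bifurcation.
    """

    segment: str
    z_start: float
    z_end: float
    volume: float
    start_distance: float

    def __post_init__(self) -> None:
        if self.z_end <= self.z_start:
            raise GeometryError(f"z_end {self.z_end} must exceed z_start {self.z_start}")
        if self.volume <= 0:
            raise GeometryError("control volume must be > 0")

    @property
    def length(self) -> float:
        return self.z_end - self.z_start


@dataclass
class ShearDistribution:
    """Volume-weighted γ̇ sample population behind the mean/Q1/Q3 metrics."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if np.any(self.weights < 0):
            raise DomainError("weights must be >= 0")

    def mean(self) -> float:
        return float(np.average(self.values, weights=self.weights))

    def quantile(self, q) -> np.ndarray:
        return weighted_quantile(self.values, self.weights, q)


@dataclass
class MetricsRecord:
    """Shear metrics of one (patient, vessel) pair; shear in 1/s, area in
    mm^2, flow in L/min.  ``ratio_mean`` is filled at patient level."""

    mean_shear: float
    q1_shear: float
    q3_shear: float
    mean_peak_shear: float
    mean_area: float
    mean_flow: float
    ratio_mean: float = math.nan


def _segment_volume(z: np.ndarray, area: np.ndarray, z1: float, z2: float) -> float:
    """∫ A dz over [z1, z2] on a refined grid (trapezoid)."""
    zz = np.union1d(np.linspace(z1, z2, 257), z[(z > z1) & (z < z2)])
    return float(np.trapezoid(np.interp(zz, z, area), zz))


def detect_stenosis_extent(
    lciv: VesselSegment,
    threshold: float = 0.9,
    flank_window: float = 5.0,
) -> Optional[ControlVolume]:
    """Locate the compressed LCIV region.

    The extent is the maximal contiguous run of stations whose area is
    below ``threshold`` times the smaller of the two uncompressed flank
    reference areas.  Each reference is the mean area over a
    ``flank_window`` mm window at the proximal/distal end of the segment:
    the narrowing must lie strictly inside the vessel, so the end windows
    are guaranteed uncompressed, whereas windows abutting the detected run
    would bleed into its smooth ramps and bias the reference low.  Returns
    None when no station is sub-threshold (control-type vessel); raises
    :class:`AmbiguousStenosisError` when several disjoint runs exist.
    """
    z, area = lciv.arclength_grid, lciv.area_profile
    if len(z) < 3:
        raise GeometryError("segment needs >= 3 stations")
    if flank_window <= 0 or 2 * flank_window >= lciv.length:
        raise GeometryError("flank windows must fit inside the segment")

    def flank_mean(lo: float, hi: float) -> float:
        lo, hi = max(lo, z[0]), min(hi, z[-1])
        zz = np.linspace(lo, hi, 64)
        return float(np.mean(np.interp(zz, z, area)))

    lo_ref = flank_mean(z[0], z[0] + flank_window)
    hi_ref = flank_mean(z[-1] - flank_window, z[-1])
    ref = threshold * min(lo_ref, hi_ref)
    runs = _contiguous_runs(area < ref)
    if not runs:
        return None
    if len(runs) > 1:
        raise AmbiguousStenosisError([(float(z[i]), float(z[j])) for i, j in runs])
    i, j = runs[0]
    z1, z2 = float(z[i]), float(z[j])
    return ControlVolume(
        segment=lciv.name,
        z_start=z1,
        z_end=z2,
        volume=_segment_volume(z, area, z1, z2),
        start_distance=lciv.origin_distance + (z1 - z[0]),
    )


def _contiguous_runs(mask: np.ndarray) -> list:
    """Index pairs (first, last) of each True run."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _solve_z_end(segment: VesselSegment, z_start: float, target_volume: float) -> float:
    """Invert the cumulative volume V(z) − V(z_start) = target (monotone)."""
    z, area = segment.arclength_grid, segment.area_profile
    if z_start < z[0] - 1e-9 or z_start >= z[-1]:
        raise GeometryError(
            f"required start {z_start:.2f} mm is outside {segment.name} "
            f"[{z[0]:.2f}, {z[-1]:.2f}]"
        )
    zz = np.union1d(np.linspace(z_start, z[-1], 2049), z[z > z_start])
    aa = np.interp(zz, z, area)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (aa[1:] + aa[:-1]) * np.diff(zz))])
    if target_volume > cum[-1]:
        raise GeometryError(
            f"{segment.name} too short: available volume {cum[-1]:.1f} mm^3 "
            f"from z={z_start:.2f} mm, need {target_volume:.1f} mm^3 "
            f"(shortfall {target_volume - cum[-1]:.1f} mm^3)"
        )
    return float(np.interp(target_volume, cum, zz))


def matched_contralateral_cv(lciv_cv: ControlVolume, rciv: VesselSegment) -> ControlVolume:
    """RCIV control volume with the same start distance from the common
    iliac bifurcation and the same volume as the LCIV one."""
    z_start = rciv.arclength_grid[0] + (lciv_cv.start_distance - rciv.origin_distance)
    z_end = _solve_z_end(rciv, z_start, lciv_cv.volume)
    return ControlVolume(
        segment=rciv.name,
        z_start=float(z_start),
        z_end=z_end,
        volume=_segment_volume(rciv.arclength_grid, rciv.area_profile, z_start, z_end),
        start_distance=lciv_cv.start_distance,
    )


def control_volume_for_control_group(subject_cvs: list, vessel: VesselSegment) -> ControlVolume:
    """Control-group CV: average start distance and volume of the case
    (Subject) control volumes, fitted into ``vessel``."""
    if not subject_cvs:
        raise GeometryError("need at least one subject control volume")
    start_distance = float(np.mean([cv.start_distance for cv in subject_cvs]))
    volume = float(np.mean([cv.volume for cv in subject_cvs]))
    z_start = vessel.arclength_grid[0] + (start_distance - vessel.origin_distance)
    z_end = _solve_z_end(vessel, z_start, volume)
    return ControlVolume(
        segment=vessel.name,
        z_start=float(z_start),
        z_end=z_end,
        volume=_segment_volume(vessel.arclength_grid, vessel.area_profile, z_start, z_end),
        start_distance=start_distance,
    )


def weighted_quantile(values, weights, q):
    """Quantiles of a weighted empirical distribution.

    Sorts the samples, places each at the normalized cumulative-weight
    midpoint (C_i − w_i/2)/W, and linearly interpolates between order
    statistics; edges clamp to the extreme samples.
    """
    v = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        raise DomainError("total weight must be > 0")
    p = (cw - 0.5 * w) / cw[-1]
    return np.interp(q, p, v)


def _cv_distribution(solution: NetworkSolution, cv: ControlVolume):
    """γ̇ samples and annular volume weights over a control volume.

    Returns ``(gamma, weights)`` with gamma (n_time, n_z, n_r) and weights
    (n_z, n_r); the weights are annular shells 2πr·Δr (trapezoid in r)
    times trapezoid Δz, and sum to the geometric control volume.
    """
    seg = solution.segments.get(cv.segment)
    if seg is None:
        raise CoverageError(f"solution stores no segment {cv.segment!r}")
    if cv.z_start < seg.z[0] - 1e-6 or cv.z_end > seg.z[-1] + 1e-6:
        raise CoverageError(
            f"control volume [{cv.z_start:.2f}, {cv.z_end:.2f}] mm outside stored "
            f"stations [{seg.z[0]:.2f}, {seg.z[-1]:.2f}] mm of {cv.segment}"
        )
    spacing = solution.options.station_spacing
    n_z = max(int(np.ceil(cv.length / spacing)) + 1, 3)
    z_cv = np.linspace(cv.z_start, cv.z_end, n_z)
    radius, gamma = solution.shear_profiles(cv.segment, z_cv)

    dz = np.full(n_z, (cv.z_end - cv.z_start) / (n_z - 1))  # trapezoid axial weights
    dz[0] *= 0.5
    dz[-1] *= 0.5
    n_r = radius.shape[1]
    dr = radius[:, -1] / (n_r - 1)
    r_w = np.full(n_r, 1.0)
    r_w[0] = r_w[-1] = 0.5
    weights = 2.0 * np.pi * radius * (dr[:, None] * r_w[None, :]) * dz[:, None]
    return gamma, weights


def cv_shear_metrics(solution: NetworkSolution, cv: ControlVolume) -> MetricsRecord:
    """Shear metrics of one control volume over the respiratory cycle.

    At every stored time the volume-weighted shear distribution over the
    control volume yields a spatial mean and weighted quartiles; the
    reported mean/Q1/Q3 are their time averages, and the mean-peak is the
    cycle maximum of the spatial mean.  ``mean_area``/``mean_flow`` are
    vessel-level clinical quantities (segment-average area, time-mean flow).
    """
    gamma, weights = _cv_distribution(solution, cv)
    w_flat = weights.ravel()
    total = w_flat.sum()
    if abs(total - cv.volume) > 5e-3 * cv.volume:
        raise GeometryError(
            f"weight closure failed: weights sum {total:.2f} vs volume {cv.volume:.2f} mm^3"
        )
    n_t = gamma.shape[0]
    means = np.empty(n_t)
    q1 = np.empty(n_t)
    q3 = np.empty(n_t)
    for i in range(n_t):
        vals = gamma[i].ravel()
        means[i] = np.average(vals, weights=w_flat)
        q1[i], q3[i] = weighted_quantile(vals, w_flat, (0.25, 0.75))
    seg = solution.segments[cv.segment]
    return MetricsRecord(
        mean_shear=float(means.mean()),
        q1_shear=float(q1.mean()),
        q3_shear=float(q3.mean()),
        mean_peak_shear=float(means.max()),
        mean_area=float(np.trapezoid(seg.area, seg.z) / (seg.z[-1] - seg.z[0])),
        mean_flow=mm3s_to_l_min(float(seg.flow.mean())),
    )


def ratio_series(
    solution: NetworkSolution,
    lciv_cv: ControlVolume,
    rciv_cv: ControlVolume,
):
    """LCIV/RCIV volume-mean shear ratio over the normalized cycle.

    Returns ``(normalized_time, ratio, mean_ratio)``; the scalar is the
    time-mean of the pointwise ratio.
    """
    g_l, w_l = _cv_distribution(solution, lciv_cv)
    g_r, w_r = _cv_distribution(solution, rciv_cv)
    mean_l = np.einsum("tzr,zr->t", g_l, w_l) / w_l.sum()
    mean_r = np.einsum("tzr,zr->t", g_r, w_r) / w_r.sum()
    if np.any(mean_r <= 0):
        raise DomainError("RCIV mean shear vanishes; ratio undefined")
    ratio = mean_l / mean_r
    tnorm = solution.times / solution.period
    return tnorm, ratio, float(ratio.mean())


def save_ratio_series(path, normalized_time, ratio) -> None:
    """Write a ratio time series as CSV (normalized_time, ratio)."""
    arr = np.column_stack([np.asarray(normalized_time), np.asarray(ratio)])
    np.savetxt(path, arr, delimiter=",", header="normalized_time,ratio", comments="")


def patient_metrics(
    solution: NetworkSolution,
    lciv_cv: ControlVolume,
    rciv_cv: ControlVolume,
) -> dict:
    """Convenience: metrics for both vessels plus the patient-level ratio."""
    rec_l = cv_shear_metrics(solution, lciv_cv)
    rec_r = cv_shear_metrics(solution, rciv_cv)
    _, _, ratio = ratio_series(solution, lciv_cv, rciv_cv)
    rec_l.ratio_mean = ratio
    rec_r.ratio_mean = ratio
    return {"LCIV": rec_l, "RCIV": rec_r, "ratio_mean": ratio}
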