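"""Virtual-patient generator for the bilateral iliac vein network.

The study design is a case-control comparison of iliac vein compression
(May–Thurner anatomy): the left common iliac vein (LCIV) is narrowed where
the right common iliac artery crosses it, while the right common iliac vein
(RCIV) serves as the patient's internal control.  Real inputs would be CT/MR
centerline areas plus Doppler ultrasound velocity/area measurements; this
module fabricates the same data products so the full analysis chain runs
without any imaging.

A virtual patient consists of

* seven vessel segments — IVC, RCIV, LCIV and the four inlets (external and
  internal iliac veins, REIV/RIIV/LEIV/LIIV) — each an arclength grid with a
  cross-sectional area profile;
* one periodic inflow waveform per inlet, driven by the respiratory cycle;
* ultrasound-like records (mean velocity + area at a slice) for the RCIV and
  LCIV, derived from the ground truth with multiplicative noise.

Topology is fixed: REIV+RIIV→RCIV, LEIV+LIIV→LCIV, RCIV+LCIV→IVC.  The
arclength coordinate of each common iliac vein starts (z = 0) at the
common iliac bifurcation (the iliocaval junction), matching how control
volumes are located downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .units import l_min_to_mm3s

__all__ = [
    "VESSELS",
    "INLETS",
    "StenosisSpec",
    "VesselSegment",
    "FlowWaveform",
    "UltrasoundRecord",
    "VirtualPatient",
    "PatientTemplate",
    "subject_template",
    "control_template",
    "generate_waveform",
    "generate_geometry",
    "make_virtual_patient",
    "make_cohort",
    "apply_measurement_noise",
    "save_patient_bundle",
    "load_patient_bundle",
]

VESSELS = ("IVC", "RCIV", "LCIV", "REIV", "LEIV", "RIIV", "LIIV")
INLETS = ("REIV", "LEIV", "RIIV", "LIIV")

#: Positivity floor of the multiplicative measurement-noise model.
NOISE_FLOOR = 0.05

BUNDLE_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class StenosisSpec:
    """Parameterized LCIV compression.

    ``severity`` is the fraction of the reference (flank) area removed at the
    throat, in [0, 0.95].  The narrowing spans ``length`` mm centred at
    ``center_position`` (arclength from the common iliac bifurcation).

    ``plateau_fraction`` shapes the narrowing: a flat throat occupying that
    fraction of the extent, joined to the flanks by half-cosine ramps.  The
    default 0 gives a pure cosine bump
    ``A(z) = A0·(1 − s·(1 + cos(2π(z − zc)/L))/2)``; values near 1 emulate the
    broad flattening produced by an artery lying across the vein.
    """

    severity: float
    center_position: float
    length: float
    plateau_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 0.95):
            raise InvalidParameterError(f"severity must be in [0, 0.95], got {self.severity}")
        if self.length <= 0:
            raise InvalidParameterError(f"stenosis length must be > 0, got {self.length}")
        if not (0.0 <= self.plateau_fraction < 1.0):
            raise InvalidParameterError(
                f"plateau_fraction must be in [0, 1), got {self.plateau_fraction}"
            )

    def area_factor(self, z) -> np.ndarray:
        """Multiplier on the baseline area at arclength(s) ``z``."""
        z = np.asarray(z, dtype=float)
        d = np.abs(z - self.center_position)
        half = 0.5 * self.length
        flat = 0.5 * self.plateau_fraction * self.length
        ramp = half - flat
        factor = np.ones_like(d)
        inside = d <= half
        if ramp > 0:
            x = np.clip((d - flat) / ramp, 0.0, 1.0)
        else:
            x = np.where(d <= flat, 0.0, 1.0)
        depth = self.severity * 0.5 * (1.0 + np.cos(np.pi * x))
        factor = np.where(inside, 1.0 - depth, factor)
        return factor


@dataclass
class VesselSegment:
    """One vessel: arclength grid (mm), area profile (mm^2), and the distance
    of its first station from the common iliac bifurcation (mm)."""

    name: str
    arclength_grid: np.ndarray
    area_profile: np.ndarray
    origin_distance: float = 0.0

    def __post_init__(self) -> None:
        self.arclength_grid = np.asarray(self.arclength_grid, dtype=float)
        self.area_profile = np.asarray(self.area_profile, dtype=float)
        if self.name not in VESSELS:
            raise ConfigurationError(f"unknown vessel name {self.name!r}")
        if np.any(np.diff(self.arclength_grid) <= 0):
            raise InvalidParameterError("arclength grid must be strictly increasing")
        if np.any(self.area_profile <= 0) or not np.all(np.isfinite(self.area_profile)):
            raise InvalidParameterError("area profile must be finite and > 0 everywhere")

    @property
    def length(self) -> float:
        return float(self.arclength_grid[-1] - self.arclength_grid[0])

    def area_at(self, z) -> np.ndarray:
        """Linear interpolation of the area profile."""
        return np.interp(z, self.arclength_grid, self.area_profile)

    def radius_at(self, z) -> np.ndarray:
        """Equivalent circular radius r(z) = sqrt(A(z)/π)."""
        return np.sqrt(self.area_at(z) / np.pi)


@dataclass
class FlowWaveform:
    """One period of a T-periodic volumetric flow waveform (mm^3/s)."""

    period: float
    times: np.ndarray
    flows: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flows = np.asarray(self.flows, dtype=float)
        if self.period <= 0:
            raise InvalidParameterError(f"period must be > 0, got {self.period}")
        if self.times[0] != 0.0 or self.times[-1] >= self.period:
            raise InvalidParameterError("times must span exactly [0, period)")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.mean_flow() <= 0:
            raise InvalidParameterError("waveform mean flow must be > 0")

    def mean_flow(self) -> float:
        """Time-mean over one period (trapezoid with periodic closure)."""
        t = np.append(self.times, self.period)
        q = np.append(self.flows, self.flows[0])
        return float(np.trapezoid(q, t) / self.period)

    def at(self, t) -> np.ndarray:
        """Periodic linear interpolation."""
        tm = np.mod(t, self.period)
        tt = np.append(self.times, self.period)
        qq = np.append(self.flows, self.flows[0])
        return np.interp(tm, tt, qq)

    def resample(self, n: int) -> "FlowWaveform":
        times = np.arange(n) * self.period / n
        return FlowWaveform(self.period, times, self.at(times))


@dataclass(frozen=True)
class UltrasoundRecord:
    """Doppler-like measurement: mean velocity (mm/s) and mean area (mm^2)
    at a slice (arclength in mm)."""

    vessel: str
    mean_velocity: float
    mean_area: float
    slice_position: float

    def __post_init__(self) -> None:
        if self.mean_velocity < 0:
            raise InvalidParameterError("mean_velocity must be >= 0")
        if self.mean_area <= 0:
            raise InvalidParameterError("mean_area must be > 0")

    @property
    def mean_flow(self) -> float:
        """Implied mean volumetric flow v·A in mm^3/s."""
        return self.mean_velocity * self.mean_area


@dataclass
class VirtualPatient:
    """One synthetic case: geometry, inflows, measurements, group label."""

    id: str
    group: str
    segments: dict
    inflows: dict
    us_records: dict
    seed: int
    period: float

    def __post_init__(self) -> None:
        if self.group not in ("Subject", "Control"):
            raise ConfigurationError(f"group must be Subject or Control, got {self.group!r}")
        missing = [v for v in VESSELS if v not in self.segments]
        if missing:
            raise ConfigurationError(f"missing segments: {missing}")
        missing = [v for v in INLETS if v not in self.inflows]
        if missing:
            raise ConfigurationError(f"missing inlet waveforms: {missing}")

    def total_inflow(self) -> float:
        """Sum of inlet mean flows (equals the IVC mean flow), mm^3/s."""
        return float(sum(w.mean_flow() for w in self.inflows.values()))


def generate_waveform(
    mean_flow: float,
    period: float,
    phasicity: float,
    n_samples: int = 64,
    seed: int = 0,
) -> FlowWaveform:
    """Respiratory-periodic inflow waveform Q(t) = Q̄·(1 + φ·cos(2πt/T)).

    Parameters
    ----------
    mean_flow : float
        Time-mean flow in L/min (> 0).
    period : float
        Respiratory period T in s (> 0).
    phasicity : float
        Relative modulation amplitude φ in [0, 1); φ = 0 gives a constant
        waveform and the minimum flow is Q̄·(1 − φ) > 0.
    n_samples : int
        Samples over one period (>= 8).
    seed : int
        Accepted for interface stability; the waveform family is
        deterministic, so the seed is currently unused.
    """
    if mean_flow <= 0 or period <= 0:
        raise InvalidParameterError("mean_flow and period must be > 0")
    if not (0.0 <= phasicity < 1.0):
        raise InvalidParameterError(f"phasicity must be in [0, 1), got {phasicity}")
    if n_samples < 8:
        raise InvalidParameterError("n_samples must be >= 8")
    qbar = l_min_to_mm3s(mean_flow)
    times = np.arange(n_samples) * period / n_samples
    flows = qbar * (1.0 + phasicity * np.cos(2.0 * np.pi * times / period))
    return FlowWaveform(period=period, times=times, flows=flows)


def generate_geometry(
    baseline_areas: dict,
    lengths: dict,
    stenosis: Optional[StenosisSpec] = None,
    spacing: float = 1.0,
) -> dict:
    """Build the seven segments: constant-area tubes plus the LCIV narrowing.

    ``baseline_areas`` and ``lengths`` map vessel names to mm^2 / mm.  The
    stenosis (if any) is applied to the LCIV and must lie strictly inside it.
    Common iliac veins start (z = 0) at the common iliac bifurcation; inlet
    segments start at their confluence with the parent vein.
    """
    for name in VESSELS:
        if baseline_areas.get(name, 0) <= 0 or lengths.get(name, 0) <= 0:
            raise InvalidParameterError(f"need positive baseline area and length for {name}")
    segments = {}
    for name in VESSELS:
        n = max(int(round(lengths[name] / spacing)) + 1, 3)
        z = np.linspace(0.0, lengths[name], n)
        area = np.full(n, float(baseline_areas[name]))
        if name == "LCIV" and stenosis is not None and stenosis.severity > 0:
            lo = stenosis.center_position - 0.5 * stenosis.length
            hi = stenosis.center_position + 0.5 * stenosis.length
            if lo <= 0.0 or hi >= lengths[name]:
                raise InvalidParameterError(
                    f"stenosis [{lo:.1f}, {hi:.1f}] mm must lie strictly inside "
                    f"the LCIV (0, {lengths[name]:.1f}) mm"
                )
            area = area * stenosis.area_factor(z)
        origin = 0.0 if name in ("IVC", "RCIV", "LCIV") else lengths["RCIV" if name[0] == "R" else "LCIV"]
        segments[name] = VesselSegment(name, z, area, origin_distance=origin)
    return segments


def apply_measurement_noise(true_value: float, coefficient_of_variation: float, seed) -> float:
    """Multiplicative Gaussian noise with a positivity floor.

    Returns ``true_value · max(0.05, 1 + cv·g)`` with g a standard normal
    draw.  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if true_value <= 0:
        raise InvalidParameterError("true_value must be > 0")
    if coefficient_of_variation < 0:
        raise InvalidParameterError("coefficient of variation must be >= 0")
    if coefficient_of_variation == 0:
        return float(true_value)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_normal()
    return float(true_value * max(NOISE_FLOOR, 1.0 + coefficient_of_variation * g))


@dataclass(frozen=True)
class PatientTemplate:
    """Sampling ranges and fixed settings for one study group.

    Leg flows are totals per side in L/min, split between the external and
    internal iliac inlet by ``internal_fraction``.  Uniform ranges are
    sampled per patient; a (x, x) range pins the value.
    """

    group: str
    right_leg_flow: tuple
    left_leg_flow: tuple
    severity_range: tuple
    baseline_areas: dict
    lengths: dict
    period_range: tuple = (3.0, 3.75)
    internal_fraction: float = 0.30
    phasicity: float = 0.30
    stenosis_length_fraction: float = 0.65
    stenosis_plateau_fraction: float = 0.60
    noise_cv: float = 0.05
    n_samples: int = 64

    def __post_init__(self) -> None:
        if self.group not in ("Subject", "Control"):
            raise ConfigurationError(f"group must be Subject or Control, got {self.group!r}")
        if self.group == "Control" and max(self.severity_range) > 0:
            raise ConfigurationError("Control template must have severity 0")
        if self.group == "Subject" and min(self.severity_range) <= 0:
            raise ConfigurationError("Subject template must have severity > 0")
        if not (0 < self.internal_fraction < 1):
            raise ConfigurationError("internal_fraction must be in (0, 1)")


_LENGTHS = {"IVC": 60.0, "RCIV": 60.0, "LCIV": 60.0,
            "REIV": 90.0, "LEIV": 90.0, "RIIV": 70.0, "LIIV": 70.0}

_COMMON_AREAS = {"IVC": 250.0, "REIV": 110.0, "LEIV": 110.0, "RIIV": 60.0, "LIIV": 60.0}


def subject_template(**overrides) -> PatientTemplate:
    """Compressed-LCIV (case) template.

    Leg flows bracket the reported group means (right 1.46, left 0.73 L/min,
    ±25%); the RCIV baseline equals the Subject group mean area 196.3 mm^2.
    The LCIV flank baseline 105 mm^2 with a 0.65-length, 60%-plateau
    narrowing yields a segment-mean LCIV area near the reported 72.6 mm^2 at
    mid severity.  Severity samples uniformly in [0.4, 0.8].
    """
    defaults = dict(
        group="Subject",
        right_leg_flow=(1.10, 1.82),
        left_leg_flow=(0.55, 0.91),
        severity_range=(0.4, 0.8),
        baseline_areas={**_COMMON_AREAS, "RCIV": 196.3, "LCIV": 105.0},
        lengths=dict(_LENGTHS),
    )
    defaults.update(overrides)
    return PatientTemplate(**defaults)


def control_template(**overrides) -> PatientTemplate:
    """Uncompressed (control) template: leg flows around right 0.82 / left
    0.91 L/min (±25%), baseline areas at the Control group means
    (RCIV 138.5, LCIV 131.8 mm^2), severity 0."""
    defaults = dict(
        group="Control",
        right_leg_flow=(0.62, 1.02),
        left_leg_flow=(0.68, 1.14),
        severity_range=(0.0, 0.0),
        baseline_areas={**_COMMON_AREAS, "RCIV": 138.5, "LCIV": 131.8},
        lengths=dict(_LENGTHS),
    )
    defaults.update(overrides)
    return PatientTemplate(**defaults)


def _uniform(rng: np.random.Generator, lohi) -> float:
    lo, hi = lohi
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def make_virtual_patient(config: PatientTemplate, seed: int, id: Optional[str] = None) -> VirtualPatient:
    """Sample one patient from a template, deterministically in (config, seed).

    Ground-truth flows and areas are drawn first; ultrasound records are then
    derived from the truth (v = Q̄/A at the slice) with multiplicative noise
    at the template's coefficient of variation.
    """
    rng = np.random.default_rng(seed)
    period = _uniform(rng, config.period_range)
    right = _uniform(rng, config.right_leg_flow)
    left = _uniform(rng, config.left_leg_flow)
    severity = _uniform(rng, config.severity_range)

    lciv_len = config.lengths["LCIV"]
    stenosis = None
    if severity > 0:
        stenosis = StenosisSpec(
            severity=severity,
            center_position=0.5 * lciv_len,
            length=config.stenosis_length_fraction * lciv_len,
            plateau_fraction=config.stenosis_plateau_fraction,
        )
    segments = generate_geometry(config.baseline_areas, config.lengths, stenosis)

    f_int = config.internal_fraction
    inlet_means = {
        "REIV": right * (1.0 - f_int), "RIIV": right * f_int,
        "LEIV": left * (1.0 - f_int), "LIIV": left * f_int,
    }
    inflows = {
        name: generate_waveform(q, period, config.phasicity, config.n_samples)
        for name, q in inlet_means.items()
    }

    # Ultrasound-like records for the common iliac veins.  The LCIV slice
    # sits at the stenosis throat (where Doppler interrogation targets the
    # compression); the RCIV slice at mid-vessel.
    civ_truth = {
        "RCIV": (l_min_to_mm3s(right), 0.5 * config.lengths["RCIV"]),
        "LCIV": (l_min_to_mm3s(left),
                 stenosis.center_position if stenosis else 0.5 * lciv_len),
    }
    us_records = {}
    for vessel, (qbar, z_slice) in civ_truth.items():
        area = float(segments[vessel].area_at(z_slice))
        v_true = qbar / area
        us_records[vessel] = UltrasoundRecord(
            vessel=vessel,
            mean_velocity=apply_measurement_noise(v_true, config.noise_cv, rng),
            mean_area=apply_measurement_noise(area, config.noise_cv, rng),
            slice_position=z_slice,
        )

    return VirtualPatient(
        id=id or f"{config.group}-{seed}",
        group=config.group,
        segments=segments,
        inflows=inflows,
        us_records=us_records,
        seed=int(seed),
        period=period,
    )


def make_cohort(group_template: PatientTemplate, n: int, master_seed: int) -> list:
    """Generate ``n`` patients with per-patient seeds spawned from
    ``master_seed`` (deterministic; identical master seeds give identical
    cohorts)."""
    if n < 1:
        raise InvalidParameterError(f"cohort size must be >= 1, got {n}")
    seeds = np.random.SeedSequence(master_seed).generate_state(n) % (2**31)
    return [
        make_virtual_patient(group_template, int(s), id=f"{group_template.group}-{i + 1}")
        for i, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# Patient bundle serialization (CSV geometry/waveforms + JSON manifest)

def save_patient_bundle(patient: VirtualPatient, directory) -> Path:
    """Write a patient to ``directory`` as plain-text files.

    Layout: ``geometry.csv`` (segment, z_mm, area_mm2, origin_distance_mm),
    one ``inflow_<name>.csv`` per inlet (header carries the period), and a
    versioned ``manifest.json`` with the ultrasound records and seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "geometry.csv", "w") as fh:
        fh.write("segment,z_mm,area_mm2,origin_distance_mm\n")
        for name in VESSELS:
            seg = patient.segments[name]
            for z, a in zip(seg.arclength_grid, seg.area_profile):
                fh.write(f"{name},{z:.6f},{a:.8f},{seg.origin_distance:.6f}\n")
    for name, wf in patient.inflows.items():
        with open(directory / f"inflow_{name}.csv", "w") as fh:
            fh.write(f"# period_s={float(wf.period):.17g}\n")
            fh.write("t_s,q_mm3_s\n")
            for t, q in zip(wf.times, wf.flows):
                fh.write(f"{float(t):.17g},{float(q):.17g}\n")
    manifest = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "id": patient.id,
        "group": patient.group,
        "seed": patient.seed,
        "period_s": patient.period,
        "geometry": "geometry.csv",
        "inflows": {name: f"inflow_{name}.csv" for name in patient.inflows},
        "us_records": {
            v: dataclasses.asdict(r) for v, r in patient.us_records.items()
        },
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_patient_bundle(directory) -> VirtualPatient:
    """Read a patient bundle written by :func:`save_patient_bundle`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("schema_version") != BUNDLE_SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported bundle schema {manifest.get('schema_version')!r}"
        )
    rows = np.genfromtxt(
        directory / manifest["geometry"], delimiter=",", names=True,
        dtype=None, encoding="utf-8",
    )
    segments = {}
    for name in VESSELS:
        mask = rows["segment"] == name
        segments[name] = VesselSegment(
            name,
            rows["z_mm"][mask],
            rows["area_mm2"][mask],
            origin_distance=float(rows["origin_distance_mm"][mask][0]),
        )
    inflows = {}
    for name, fname in manifest["inflows"].items():
        with open(directory / fname) as fh:
            header = fh.readline()
        period = float(header.split("=", 1)[1])
        data = np.loadtxt(directory / fname, delimiter=",", skiprows=2)
        inflows[name] = FlowWaveform(period, data[:, 0], data[:, 1])
    us_records = {
        v: UltrasoundRecord(**r) for v, r in manifest["us_records"].items()
    }
    return VirtualPatient(
        id=manifest["id"], group=manifest["group"], segments=segments,
        inflows=inflows, us_records=us_records, seed=int(manifest["seed"]),
        period=float(manifest["period_s"]),
    )
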