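# Methods

`iliacshear` is a desk-scale analysis chain for case-control studies of
iliac vein compression (May–Thurner syndrome): compression of the left
common iliac vein (LCIV) by the right common iliac artery elevates local
shear rates, and the ratio of LCIV to RCIV shear — using the contralateral
vessel as an internal control — is the candidate stratification metric.
This note documents the models, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Blood rheology

Blood is modelled as a generalized-Newtonian shear-thinning fluid with the
Carreau–Yasuda law

    μ(γ̇) = μ∞ + (μ0 − μ∞)(1 + (λγ̇)^a)^((n−1)/a)

with whole-blood constants μ∞ = 0.0035 Pa·s, μ0 = 0.16 Pa·s, n = 0.2128,
a = 0.64, λ = 8.2 s (`rheology.BLOOD`).  The shear rate is the invariant
γ̇ = √(2 D:D) of the rate-of-deformation tensor D = (∇u + ∇uᵀ)/2 — the
standard scalar fed to the constitutive law, and an index of mechanical
platelet activation (shear-dependent platelet aggregation is triggered
around 1,000 s⁻¹).

The stress law τ(γ̇) = μ(γ̇)·γ̇ is provably strictly increasing for any
admissible parameter set: writing x = (λγ̇)^a and m = (n−1)/a,

    dτ/dγ̇ = μ∞ + (μ0 − μ∞)(1 + x)^(m−1) (1 + n·x) > 0  for n > 0.

A dense numerical scan at construction re-verifies this as a safety net;
the inverse γ̇(τ) used by the profile solver is therefore single-valued.
Stress inversion uses safeguarded bisection on the bracket
[τ/μ0, τ/μ∞], 60 halvings (relative width far below 1e−10).

Gridded shear-rate fields use second-order central differences in the
interior and first-order one-sided stencils on boundaries
(`numpy.gradient`, edge order 1); each axis needs ≥ 3 nodes.

## Reduced-order hemodynamics

The headline modelling simplification: the three-dimensional unsteady
finite-element problem is replaced by a **quasi-steady, fully developed,
axisymmetric (generalized-Poiseuille) model** per arclength station.  At
venous scales the Womersley number is low and the respiratory driver slow,
so the flow tracks the boundary conditions almost statically.  The model
omits secondary flows, post-stenotic jets and non-circular (flattened)
lumens; **absolute shear magnitudes are therefore surrogates** — the
compressed vein's true slit-like cross-section carries substantially
higher wall shear than the equivalent circular tube — while severity
trends and left/right ratios are preserved.  Absolute per-patient values
from the source cohort are consequently only exercised through the
printed-value fixture, never re-derived.

Per station (radius R from A = πR², rigid no-slip wall) and time sample,
momentum balance gives the linear stress profile τ(r) = G·r/2; the solver
finds the axial pressure gradient G such that

    Q = 2π ∫₀ᴿ r·u(r) dr,   u(r) = ∫_r^R γ̇(s) ds,   γ̇(r) = τ⁻¹(G·r/2)

matches the prescribed flow.  `solve_generalized_poiseuille` does this
directly (Simpson quadrature on an n_radial = 128 node grid, Brent
iteration on G to 1e−10 relative, Newtonian bracket
[8μ∞Q/πR⁴, 8μ0Q/πR⁴]); composite Simpson is exact for the Newtonian
(parabolic) limit, so the closed forms u(r), γ̇_w = 4Q/(πR³) are
reproduced to solver precision, and wall shear changes by < 0.1% when the
radial grid doubles.

Bulk evaluation across all (station, time) pairs uses the Rabinowitsch
reduction: integrating by parts, Q = πR³·I(τ_w)/τ_w³ with
I(τ_w) = ∫₀^{τ_w} s²γ̇(s) ds, so the single monotone function
J(τ_w) = I(τ_w)/τ_w³ maps Q/(πR³) to wall stress for every radius at
once.  J is tabulated once per rheology (4096-node logarithmic grid,
cumulative Simpson in log-space, analytic Newtonian tail below the grid)
and interpolated with monotone log-log cubics; a regression test pins this
path to the direct solver at 1e−6.

Flows are routed by conservation through the fixed topology
REIV+RIIV→RCIV, LEIV+LIIV→LCIV, RCIV+LCIV→IVC (inflows prescribed at the
four inlets).  Pressure is assembled from the outlet upward by
accumulating G = 2τ_w/R along each path, so it decreases monotonically in
the drainage direction whenever flow is positive.

### Windkessel outlet

The infrarenal IVC carries a three-element (RCR) Windkessel:
C·dP_c/dt = Q − (P_c − P_ref)/R_d, P = R_p·Q + P_c, integrated with
classical RK4 at dt = 0.01 s (the reduced system is not stiff at venous
time constants; sub-millisecond steps are an FEM stability concern, not
needed here) for 4 cycles, keeping the last.  The state starts at its
cycle-mean fixed point so the discarded first cycle absorbs the residual
transient.  In periodic state the capacitor carries no mean current, so
the cycle-mean pressure is exactly P_ref + (R_p + R_d)·Q̄; `tune_windkessel`
exploits this to size R_total = (target − P_ref)/Q̄ for the 10 mmHg
(1333.22 Pa) venous target.  The proximal:distal split is 5%:95%,
reverse-engineered from the reported group-average resistances
(0.00187/0.0355 and 0.00237/0.0451 mm-g-s, both ≈ 5.0% proximal); the
reference pressure defaults to 0 (gauge venous reference).  Both choices
are open in the source material and are ours.

Units are mm–g–s throughout (pressure ≡ Pa), with fixed conversions
1 L/min = 16 666.7 mm³/s and 1 mmHg = 133.322 Pa.

## Control volumes and shear metrics

The stenotic LCIV control volume is the contiguous region whose area
falls below 90% of the uncompressed reference area, taken as the smaller
of the proximal and distal flank references (the conservative, both-sided
reading).  Flank references are the mean area over 5 mm windows at the
segment ends: the narrowing must lie strictly inside the vessel, so the
end windows are guaranteed uncompressed, whereas windows abutting the
detected region would bleed into its smooth ramps and bias the reference
low (shrinking the extent away from the analytic 90% crossing — verified
against closed-form bounds on the cosine narrowing).  Several disjoint
sub-threshold runs raise an ambiguity error listing the runs.

The RCIV control volume starts at the same distance from the common iliac
bifurcation and encloses an identical volume, found by monotone inversion
of the cumulative volume ∫A dz (0.1% closure).  Control-group patients
have no stenotic extent; their control volumes inherit the average size
and start distance of the case group's.

Within a control volume, shear samples come from the reconstructed radial
profiles of every station (spacing 1 mm), weighted by annular volume
2πr·Δr·Δz with trapezoid end-weights so the weights sum exactly to the
geometric volume (0.5% closure enforced).  Metrics:

* **mean** — volume-weighted mean γ̇, time-averaged over the cycle;
* **Q1/Q3** — weighted quartiles (weighted empirical distribution,
  cumulative-midpoint positions, linear interpolation between order
  statistics; with equal weights this is the Hazen convention),
  time-averaged;
* **mean peak** — the cycle **maximum of the spatial (volume-weighted)
  mean**, not the spatial mean of per-node temporal maxima.  Both
  readings are defensible; this one was chosen because the spatial mean
  is the quantity plotted over the cycle and its peak is what the
  1,000 s⁻¹ platelet-activation threshold is compared against;
* **LCIV/RCIV ratio** — the pointwise-in-time ratio of the two volume
  means over the normalized cycle; the scalar is its time mean.

The closed-form anchor: steady Newtonian flow in a uniform cylinder has
γ̇(r) = γ̇_w·r/R, volume CDF F(γ) = (γ/γ̇_w)², hence mean/Q1/Q3 =
(2/3, 1/2, √3/2)·γ̇_w; the full chain reproduces these to 1% at default
resolution.

## Synthetic cohort

No real data ship with the package; the generator fabricates the same
data products imaging and Doppler ultrasound would provide.  Defaults are
anchored to the study conditions: 4 cases + 4 controls; leg mean flows
sampled ±25% around the reported group means (cases right 1.46 / left
0.73 L/min; controls right 0.82 / left 0.91); RCIV baselines at the
reported group-mean areas (196.3 / 138.5 mm²); control LCIV 131.8 mm²;
respiratory period sampled from the reported 3.0–3.75 s range;
capacitances 22.4 / 12.6 mm³/Pa; severity uniform in [0.4, 0.8] for
cases, 0 for controls.

The compression model is a cosine-tapered narrowing with an optional flat
throat: severity s removes the fraction s of the flank area at the
throat, a plateau occupies `plateau_fraction` of the extent, and
half-cosine ramps join it to the flanks (`plateau_fraction = 0` is a pure
cosine bump).  The case template uses plateau fraction 0.6 over 65% of
the LCIV with a 105 mm² flank baseline: an artery lying across a vein
flattens it over a finite length rather than pinching a point, and these
values put the segment-mean LCIV area near the reported case mean of
72.6 mm² at mid severity — a pure cosine bump cannot reach that mean area
with any credible flank baseline.

Inflow waveforms are Q(t) = Q̄(1 + φ·cos(2πt/T)) with phasicity φ = 0.3;
the internal:external iliac split is 30:70.  Neither quantity is reported
in the source material; both are stand-in choices, configurable per
template.  Measurement noise is multiplicative Gaussian,
value·max(0.05, 1 + cv·g), cv = 0.05 by default; ultrasound-like records
derive from the ground truth (v = Q̄/A at the slice) before noising.

What the generator does **not** emulate: non-circular lumens, vessel
taper and curvature, collateral drainage, waveform shape variability,
hydration-dependent caliber drift between scan dates, or any imaging
noise.  Passing synthetic tests therefore demonstrates that the pipeline
recovers relative case-control structure (ratio contrast, severity
monotonicity, extent detection) under its own stated noise model — not
that it reproduces patient-specific absolute shear rates.

## Calibration

Boundary conditions are reconciled with the ultrasound-like measurements
by a fixed-point loop (flows → pressure → areas, up to 20 iterations):

1. scale each side's inlet waveforms so the simulated common-iliac mean
   flows match the measured ones (v·A per record, overridable) — routing
   is conservative, so the exact scale is available in closed form;
2. retune the Windkessel to the 10 mmHg mean-pressure target;
3. blend the imaging area toward the ultrasound area per vessel,
   A = w·A_ct + (1−w)·A_us, by monotone bisection on w so the slice
   velocity Q̄/A matches the measured velocity within 10%.

Convergence (flows 2%, velocity 10%, pressure 2%) is declared only when
all criteria hold on a fresh simulation of the final state; infeasible
targets (no admissible w) produce a diagnostic non-converged result, not
an exception.  A per-inlet freeze flag excludes an inlet from flow
scaling, mirroring cases where one inlet's boundary condition was never
tuned.

## Statistics

Within-group RCIV-vs-LCIV comparisons use two-sided paired Student t
tests (df = n−1); between-group comparisons use two-sided homoscedastic
(pooled-variance) t tests (df = n1+n2−2).  p-values come from the exact t
distribution via the regularized incomplete beta; at df = 6 the headline
ratio comparison sits near 8×10⁻⁵, where a normal approximation is
useless.  No multiple-testing correction is applied, matching the source
analysis.  Zero-variance conventions (all-zero paired differences → p = 1;
zero pooled variance with unequal means → p = 0 with a degeneracy flag)
are this package's own.

A bundled, checksummed fixture carries the printed per-patient table
values.  `reproduce_paper_statistics` recomputes every derivable summary
and compares at printed precision: mean/std cells must reproduce the
printed string after half-up rounding of the float64 value (which also
reproduces quirks like 131.85 → 131.8, since the stored double is
131.8499…, and 26.5 → 27); p-values match at their printed decimals or,
failing that, at two significant figures — the printed p columns mix one
to five decimals and three five-decimal cells are not exactly recoverable
from the printed per-patient inputs (0.01218, 0.24318, 0.39748 vs exact
0.01219, 0.24281, 0.39728), presumably upstream rounding.

## Problem sizes and determinism

Default resolutions: 1 mm stations, 64 time samples per cycle, 128 radial
nodes, dt = 0.01 s, 4 Windkessel cycles — one patient simulates in well
under a second and a full calibrated 4+4 study with a five-point severity
sweep runs in seconds on one core.  All randomness flows through
`numpy.random` generators seeded from explicit integers; identical seeds
give byte-identical serialized cohorts.  The severity sweep regenerates
one template patient at each severity with the same seed so flows, period
and noise draws coincide.

## Known limitations

* Circular cross-sections under-predict shear in flattened compressed
  segments; the ratio contrast recovered synthetically (typically 3–4.5×
  between case and control group means across seeds) is smaller than the
  4.6× reported from image-based models, and with an unlucky low-severity
  draw a 4-patient group can fall below 3×.
* Quasi-steady profiles ignore inertia and entrance effects; the model
  has no wall compliance, no collaterals, and no thrombus burden.
* The calibration loop is a plausible reconstruction; the original
  tuning procedure's order and stopping logic are not documented.
* Quartile weighting (volume vs node count) and the "mean peak" reading
  are documented choices; both alternatives are one-line switches on the
  shear distribution.
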