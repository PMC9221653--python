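# Methods

## Field model

The magnet is an axially magnetised cylinder (radius k, length l,
magnetisation M₀), reduced to a point dipole of moment m = M₀·π·k²·l at its
centre:

B(P) = (μ₀ μ_r / 4π) · m · [3⟨o, R⟩R/‖R‖⁵ − o/‖R‖³],  R = P − p.

μ_r is fixed to 1 (human tissue is magnetically transparent) and is not a
parameter. Internally everything is SI (m, T, A/m); millimetres and
microtesla exist only in file formats and printed output.

The point-dipole reduction is an approximation whose error is the
finite-size (quadrupole and higher) correction. `finite_volume_field`
quantifies it by superposing sub-dipoles on an equal-volume cylindrical
grid (equal-area radial shells × angular sectors × axial slabs, sub-dipole
at each cell's centroid; one cell degenerates exactly to the point dipole).
For the 10×10 mm magnet the deviation is below 1% beyond five magnet
lengths and below 0.1% at the ≥100 mm sensor distances. For the 5×10 and
3×10 magnets the *diameter* is the controlling dimension: at five
diameters the worst-case (axial) deviation is 1.0–1.3%, falling as 1/R² to
roughly 0.3% at sensor distances. The localiser knowingly fits the dipole
model; this residual model error is part of what the tracking errors
measure.

## Sensor array and measurement chain

Twelve three-axis magnetometers sit at parametric angles 0/90/180/270° on
three ellipses with semi-axes 200 mm (x) and 165 mm (y), ring planes at
z = −100/0/+100 mm. The placement angles are a configuration choice
(symmetric coverage); all sensors share one orientation frame so that
every one of the C(12,2) = 66 unordered pairs is "equally oriented". A
disjoint 6-pair mode (outer rings paired across at equal angle, middle
ring across the centre) exists for ablation; the default is all 66 pairs,
giving 198 residuals for 6 unknowns.

Each reading passes a simulated ADC chain, in this order: add the
homogeneous background, add per-axis Gaussian noise, clip to ±800 µT,
round to the nearest 32 nT LSB, average n = 3 samples. The noise default
σ = 0.3 µT per axis *before* averaging is a representative magnetometer
noise floor (the effective per-reading σ is 0.3/√3 ≈ 0.17 µT); it is
configurable and the error budget scales with it. With quantisation
enabled, raw samples are exact LSB multiples; 3-sample averages are
multiples of LSB/3, so the "integer multiples of the LSB" property is
asserted for single-sample (or zero-noise) frames only.

## Calibration

Hard-iron (additive) and soft-iron (linear) distortions are identified by
an algebraic quadric least-squares fit: the smallest-singular-vector
solution of the 10-parameter quadric design matrix on scale-normalised
samples, an explicit ellipsoid check (all quadric eigenvalues positive,
real radii), centre extraction, and the symmetric positive-definite matrix
square root. The SPD root resolves the rotational ambiguity of ellipsoid
fits; the calibration is per sensor. The reference radius defaults to the
48 µT local field magnitude — the fit determines the ellipsoid only up to
scale, so some normalisation target must be chosen. Degenerate sample sets
(< 9 points, coplanar sweeps, non-ellipsoid quadrics) raise typed errors
rather than returning garbage.

The calibration module is exercised against a forward-distortion
generator; the simulated measurement chain itself is clean, so calibration
is not in the default tracking loop.

## Pose estimation

Six unknowns: position plus a free orientation 3-vector, normalised inside
the field model and on output. This keeps the problem smooth (no angle
wrapping) at the cost of a gauge direction that LM handles without
trouble. The moment magnitude is taken from the magnet catalog, not
estimated. Residuals are the 66 pair differences (measured difference
minus model difference, in that order — the measured difference is formed
first so the homogeneous term cancels before any model value is
subtracted); they are scaled to µT inside the optimiser for conditioning.
MINPACK Levenberg–Marquardt runs with ftol 1e−10, xtol/gtol 1e−14 and a
budget of 200 iterations per start.

Cold starts rank a coarse grid (5×5×5 positions spanning ±150/±120/±100 mm
× 6 axis-aligned orientations) by differential cost and LM-refine the best
five. Warm starts (tracking) use the previous estimate. The dipole's axial
sign is unobservable; estimates are reported in the hemisphere of the
initial orientation, which during tracking becomes continuity with the
previous frame.

`solve_standard` is the non-differential baseline: per-sensor residuals
minus an *assumed* background. It matches the differential solve when the
assumption is correct and degrades when it is stale — the comparison that
motivates the differential formulation.

## Trajectory generator

The physical track is known only through summary numbers: 487.5 mm arc
length, ~15° tilt, 49 mm vertical rise, a 180 × 180 mm footprint, 40 s per
traversal, non-uniform hand speed. The preset (`serpentine-v1`) realises
them as a three-half-lobe sinusoid v(u) = A·sin(3πu/U) in a plane tilted
about the lateral axis. The footprint (180 mm) and rise (49 mm) are taken
as exact, which fixes the tilt at atan(49/180) = 15.22°; the amplitude A
(≈ 73 mm) is solved numerically (Brent) so the arc length is 487.5 mm to
twelve digits. A two-lobe sinusoid cannot hold this arc length inside the
footprint (it would need a 226 mm lateral span), which is why the preset
uses three half-lobes. Note the three stated constraints 15°/49 mm/180 mm
are mutually inconsistent by ~3 mm of footprint; the generator resolves
the conflict in favour of the two quantities the evaluation actually
scores (arc length, vertical displacement).

Sampling: 100 poses per traversal by default (configurable), uniform in
arc length, with interior samples perturbed by up to ±30% of the mean
spacing (`jitter = 0.3`) to emulate hand motion; timestamps are uniform
over 40 s. The magnet axis is perpendicular to the local tangent by
default (tangent × ẑ, renormalised; tangent × x̂ fallback for vertical
tangents), or parallel in the 10×10 magnet's second mode. Parallel mode
for the 3/5 mm magnets requires an explicit override, mirroring the
physical impossibility of moving them that way along the track wall.

What the generator does *not* emulate: peristaltic dynamics, capsule–wall
contact, sensor placement error, soft-tissue field distortion, or a
moving/rotating patient (the background stays homogeneous and constant).
Passing tests therefore demonstrate the estimator's behaviour under the
stated noise model, not in vivo performance.

## Tracking and evaluation

Frame 0 is solved cold, later frames warm-start from the previous
estimate. A warm-started fit whose final cost exceeds 50× the running
median has fallen into a spurious minimum (observed rarely, when LM takes
a wild step from an otherwise good init); it is re-solved from a cold
start and the lower-cost solution kept. Frames whose solver did not
converge are flagged, excluded from the orientation mean, and contribute
their last converged position to the distance sum.

Traveled distance is the chordal sum over estimated positions, compared
with the same sum over the ground-truth samples: with position noise the
estimate is biased long (a chord with noisy endpoints is longer in
expectation), so the relative distance error is one-sided in practice.
Orientation error is the axis angle arccos|⟨e, r⟩| per sample (the axial
sign is unobservable; a signed mode exists), averaged over converged
frames; `tilt_angle_error` provides the secondary tilt-referenced reading
(estimated axis elevation out of the horizontal plane minus the nominal
track tilt) for comparability with protocols that reference the physical
track angle.

The full protocol is 5 repeats × 3 z planes × 2 layouts = 30 runs per
magnet configuration, each run seeded by a child of the master seed
(`numpy` SeedSequence spawning), summarised as mean ± sample STD (ddof 1;
a single-run design reports STD 0). At the default 100 samples per run the
protocol for one magnet takes ~1 minute on one CPU; the problem sizes in
the tests (25–100 samples, 1–5 repeats) were chosen to keep full-pipeline
checks cheap while exercising every code path.

## Numerical conventions and edge cases

* Exact geomagnetic invariance: in real arithmetic the residuals are
  invariant under adding any constant vector to all readings. In floating
  point this is bitwise true whenever the shifted readings are exactly
  representable (e.g. dyadic grids); for arbitrary doubles the discrepancy
  is a few ULPs (≲1e−18 T), far below the 32 nT LSB.
* Zero-distance field evaluations, zero orientation vectors, empty
  position lists, non-increasing timestamps, under-determined systems and
  empty grids raise `ValueError` rather than propagating NaNs.
* `lsb = 0` disables quantisation (used by oracles); `SensorModel.ideal()`
  is the noise-free unquantised chain.
* Clipping to full scale is silent but logged (`logging` warning with the
  clipped-sample count).
* Arc-length calibration and resampling use a 200,001-point dense
  polyline; its discretisation error (<1e−5 mm) is negligible against the
  0.1 mm tolerances used in tests.
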