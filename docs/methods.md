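# Methods

This note documents the models, conventions and design choices behind
`panobreast`, in the order the pipeline runs.

## World frame and resampling

All volumes live in a fixed RAS-style frame relabeled anatomically:
axis 0 = left–right (LR), axis 1 = anterior–posterior (AP, + = anterior),
axis 2 = head–foot (HF), in mm. NIfTI input is reoriented to this frame at
read time (`nibabel.as_closest_canonical`), so no other module inspects
orientation. Images are sampled with trilinear interpolation, segmentations
with nearest-neighbor, everywhere; points outside the field of view return 0
(not NaN), keeping downstream statistics finite. Sampling at an exact voxel
center reproduces the stored value (`scipy.ndimage.map_coordinates`, order 1,
no prefilter).

The symmetry-optimizing rotations are deliberately not a full rigid
registration: a 1D grid search (default ±10°, 1° steps, ties toward 0°) about
a single axis — HF (yaw) for the first rotation, AP for the coronal-view
second rotation — maximizing the normalized cross-correlation between the
volume and its LR mirror. This is deterministic, matches the "linear
transform" role the workflow assigns to these steps, and recovers an applied
rotation to within one grid step at voxel sizes ≤ 6 mm (coarser grids can be
biased by one step by discretization).

## Phantom

The synthetic subject is built from solids with closed-form geometry so that
curve lengths and tissue volumes are testable analytically:

* **Torso**: elliptic cylinder, half-width 150 mm (LR), half-depth 90 mm
  (AP), length 256 mm (HF), with a gentle anterior "chest bow"
  (12 mm × (2z/L)²) so the sternum line is genuinely curved in the sagittal
  plane.
* **Breasts**: two hemispheres (default radius 55 mm, centers 120 mm apart on
  the chest wall), cut by the axial-ish plane through their centers so each
  holds exactly (2/3)πr³; a fibroglandular core at 0.6 r inside a fat shell;
  optional spherical lesions validated to lie inside breast tissue. The
  default total breast volume (~0.70 L) emulates a small-breasted subject
  within the 0.5–3.0 L range of the study population, where the panoramic
  benefit is largest.
* **Signals**: piecewise constant — fat 1.0, fibroglandular 0.85, lesion 1.4,
  background 0 — mimicking an acquisition tuned for low fat/water contrast.
* **Curves**: the sternum curve is the midsagittal anterior surface
  (analytic); the breast contour is a scaled-ellipse arc spanning 140° in the
  axial plane through the breast centers, passing mid-tissue (half the breast
  protrusion above the chest wall).
* **Grid**: 4 mm isotropic by default (a deliberate desk-scale choice; tests
  use 5–8 mm where geometry, not resolution, is under test).

What the phantom does *not* emulate: tissue relaxometry and sequence
contrast, gravity deformation, B1+ inhomogeneity, coil coupling. Passing
tests therefore validate the *computational* pipeline — geometry, noise
statistics, reconstruction identities — not in-vivo SNR magnitudes. The
in-vivo headline numbers (≈3-fold gain, 6×4 acceleration, 2–4× slice
reduction) have qualitative analogues here, not reproductions.

## Coil array and sensitivities

The conformal array puts 7 columns of loops around the chest arc (±63°
azimuth) × 4 rows along HF (28 channels), radius 40 mm, centers 5 mm anterior
of the skin, loop axes pointing into the body. A retracted variant
(`standoff_mm=65`) serves as the reference for the SNR-gain analogue.

Per-channel sensitivity magnitude is the Biot–Savart field of the loop
discretized into 64 straight segments (distance clamped to a 1 mm core so
the field is finite on the wire; μ0I/4π = 1, units arbitrary). A smooth
channel-specific linear phase (0.01 rad/mm along a per-channel direction)
makes the maps complex and non-collinear. The on-axis field matches the
closed form 2πR²/(R²+d²)^{3/2} to < 1%.

## Noise model and SNR conventions

Channel noise is circular complex Gaussian with E[n nᴴ] = Ψ; real and
imaginary parts are independent with covariance Ψ/2 each. Draws use the
Cholesky (or eigen) square root of Ψ. The default construction is uniform
correlation: unit diagonal, off-diagonals ρ = 0.065, matching the array's
6–7% mean normalized correlation; optional phase jitter is re-projected to
the PSD cone by eigenvalue clipping plus congruence rescaling.

SNR is magnitude over **per-quadrature** noise SD:
σ̂² = (var(Re) + var(Im))/2 over replicas, so a single channel with unit
total noise variance and signal 10 has SNR = 10√2. Both SNR paths share this
convention exactly:

* `analytic_snr`: SNR = |wᴴp| / sqrt(wᴴΨw / 2); for the matched filter this
  reduces to sqrt(2 pᴴΨ⁻¹p).
* `pseudo_replica_snr`: noise replicas are propagated through the per-voxel
  *effective linear weights* recorded at combine time. For the
  whitened-root-sum-of-squares combiner (default; needs no sensitivity
  estimate) the magnitude is nonlinear, so its first-order weights
  w = Ψ⁻¹p/‖L⁻¹p‖ are what noise propagates through — the same linearization
  the closed form uses. For the matched filter, w ∝ Ψ⁻¹s with wᴴs = 1, and
  the propagation is exact. 256 replicas (default) give ≈3% median agreement
  with the oracle; 64 replicas ≈5%.

The simulated acquisition's noise level (σ = 5·10⁻⁴ in sensitivity units by
default) puts the breast-ROI SNR in the hundreds, the regime of a modern
breast GRE protocol, where the magnitude bias of the noisy numerator is
negligible.

## SENSE g-factors

Cartesian undersampling by (R_LR, R_HF) aliases voxels offset by FOV/R in
each accelerated direction. Aliasing sets are restricted to the object
support (a flag disables this), and the slice is zero-padded to the next
multiple of R when the matrix size does not divide. For each set with
sensitivity matrix S: g_ρ = sqrt([(SᴴΨ⁻¹S)⁻¹]_ρρ [SᴴΨ⁻¹S]_ρρ). Sets whose
smallest singular value falls below 10⁻¹⁰ of the largest are unresolvable and
carry +∞; voxels outside support are NaN.

The accelerated-acquisition noise carries covariance R·Ψ (the image-domain
consequence of sampling 1/R of k-space under a unitary DFT), which makes the
identity SNR_R = SNR_full/(g√R) exact for the matched-filter/SENSE pair and
lets the pseudo-replica g-factor (fold → unfold → replicate) agree with the
closed form to Monte-Carlo precision.

g is guaranteed non-decreasing only when one acceleration's aliasing sets
nest inside the other's (R divides R′ in one direction): on the study grid
{2,4,6,8} × {2,4,6} that covers 2|4|8 and 2|6, and the maps do show e.g. a
higher max g at R_LR = 6 than at R_LR = 8 on some slices — a real property of
non-nested partitions, not an artifact.

`max_acceleration` returns the candidate with the largest product whose max g
over the ROI stays below the threshold (default 2), breaking ties toward
larger R_LR where the array has more channels.

## Panoramic reconstruction

Curves are interpolating natural cubic splines through the control points,
re-parameterized by arc length (uniform table at ≤ 0.5 mm; chord-sum length
accurate to ≈10⁻⁵ relative on a semicircle). The CPR is the *straightened*
variant: output voxel (carried, depth, s) samples curve(s) + depth·n(s),
where the in-plane unit normal n is the tangent rotated +90° within the
curve's plane, globally oriented anterior. Because both curves are planar,
the frame is continuous by construction (no parallel transport needed).
A depth range exceeding the minimum radius of curvature makes normal lines
cross; this is recorded in the transform's provenance and warned about, but
sampling proceeds (the drawn contour is expected to be mild; the default
symmetric depth range of ± half the source AP extent triggers the warning on
strongly curved contours by design).

The full transform composes rot1 → CPR_sag → CPR_ax → rot2 lazily and
resamples the source once per output voxel; a `cascaded=True` mode resamples
per stage for comparison (it accumulates interpolation loss and is not the
default). Output spacing defaults to the smallest source spacing. The
flattened extents equal ceil(arc length / spacing) + 1 voxels, so distances
along the drawn curves are preserved in the panorama.

The contour curve is supplied in source world coordinates and mapped into the
stage-1 frame internally (rotation + curve-plane projection); both curves'
plane constraints (sagittal / axial to within one voxel) are validated.

## Slice metrics

"Contains tissue" means strictly more than `min_voxels` (default 10)
segmented voxels in the slice. Counting axes: HF for axial views, AP for
coronal and panoramic views (the flattened-depth direction). Tight crops
apply the same rule per axis and are reported in voxels and mm on all three
axes. Reduction factors are reference count / panoramic count. Breast volume
is voxel count × voxel volume / 1000 (mL).

On the default phantom the axial-vs-panoramic factor is 1.80 (27 → 15
slices at 4 mm), kept as a regression value; the magnitude is
phantom-dependent, only the direction (> 1.5) is a stable claim.

## Statistics

`paired_onesided_ttest` is the classical paired t on differences (upper
tail, df = n−1), guarded against zero difference variance.
`required_sample_size` iterates n upward computing one-sided (or two-sided)
paired-t power from the noncentral t distribution (ncp = d√n), then inflates
by dividing by (1 − dropout) and rounding up: d = 1, α = 0.05, power 0.8
gives n = 8, and a 20% dropout rate inflates it to 10.
`standardized_effect_size` converts a detectable relative difference and
relative SD to Cohen's d: (1.2 − 1)/0.2 = 1.

## Known limitations

* Noise is added in image space; for Cartesian sampling and linear
  reconstruction the SNR and g-factor statistics are equivalent to k-space
  simulation, but k-space-domain effects (regridding, partial Fourier,
  GRAPPA kernels) are out of scope.
* The whitened-RSS pseudo-replica path is a first-order linearization; at
  ROI SNR below ~10 the magnitude bias becomes visible.
* The symmetry search is 1-DoF per rotation; genuinely tilted subjects would
  need full rigid registration.
* The mirror image for the symmetry score is taken in index space, which
  coincides with the world-space LR mirror for axis-aligned affines (always
  true after canonical reorientation with axis-aligned acquisitions).
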