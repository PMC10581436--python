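# panobreast

Panoramic supine breast MRI reconstruction and receive-array evaluation on a
synthetic torso phantom.

## The problem

Breast MRI is normally acquired prone with a rigid breast coil. Supine
acquisition — enabled by flexible, conformal receive arrays worn like a bra —
is more comfortable and matches the positioning of ultrasound and surgery, but
the breast tissue then spreads along the curved chest wall, so many more
Cartesian slices contain tissue and reading gets slower. Two things are needed
to make supine breast MRI practical:

1. a **panoramic view** that flattens the curved tissue slab into a few
   slices, analogous to a dental panoramic radiograph, and
2. a quantitative **coil-array evaluation**: per-voxel SNR maps, noise
   correlation, parallel-imaging g-factors, and reading-efficiency metrics.

`panobreast` implements both, exercised end to end on an analytic
torso/breast phantom with a conformal 28-channel loop array (7 four-channel
modules, 8 cm loops) so every pipeline stage can be checked against closed
forms.

## Methods at a glance

**Panoramic reconstruction.** The output grid is mapped to the source volume
through the composition

```
T = T_rot,1 ∘ T_sag ∘ T_ax ∘ T_rot,2
```

where `T_rot,1` maximizes left–right mirror symmetry, `T_sag` is a
straightened curved planar reformatting (CPR) along a sternum spline `C_sag`
drawn in the midsagittal plane (flattening head–foot), `T_ax` is a second CPR
along a breast-contour spline `C_ax` drawn on the axial slice through the
fullest breast section (flattening left–right), and `T_rot,2` re-optimizes
symmetry in the coronal view. The composition is evaluated lazily so each
output voxel samples the source exactly once. Straightened CPR preserves
distances along the drawn curve: the flattened axis is indexed by arc length.

**SNR mapping.** The pseudo multiple replica method: synthetic channel noise
with the measured covariance `Ψ` is propagated through the exact channel
combination many times, and `SNR(r) = |combined(r)| / σ̂(r)` with `σ̂` the
per-quadrature noise SD over replicas. A closed-form oracle
(`SNR = |wᴴp| / sqrt(wᴴΨw / 2)`, matched filter `SNR = sqrt(2 pᴴΨ⁻¹p)`)
validates it to a few percent at 256 replicas.

**Parallel imaging.** Ideal Cartesian SENSE with known sensitivities: the
geometry factor of voxel ρ in an aliasing set with sensitivity matrix `S` is
`g_ρ = sqrt([(SᴴΨ⁻¹S)⁻¹]_ρρ [SᴴΨ⁻¹S]_ρρ)`, and the usable acceleration is the
largest `R_LR × R_HF` on the study grid with max g < 2 over the breast ROI.

**Reading efficiency.** Slices containing more than 10 segmented breast-tissue
voxels are counted per view (axial, coronal, panoramic) after tight cropping,
and reduction factors reference/panoramic are reported, along with segmented
breast volume in mL.

## Worked example

```bash
cat > demo.yaml <<'EOF'
phantom: {voxel_spacing: 6.0}
replicas: 256
seed: 42
EOF
panobreast evaluate --config demo.yaml --out demo_out
python -m json.tool demo_out/summary.json
```

Key lines of the summary this prints (6 mm phantom, 28 channels, 256
replicas):

```
"mean_offdiag_correlation": 0.0656    # noise-only scan recovers the 6.5% design value
"roi_mean_snr": 726.08                # pseudo-replica SNR averaged over the breast ROI
"roi_homogeneity": 0.918              # SD/mean of SNR over the ROI (surface-coil falloff)
"snr_gain_vs_retracted": 3.74         # conformal array vs the same array 60 mm off the skin
"max_acceleration": {"R_LR": 4, "R_HF": 4, "product": 16, "g_threshold": 2.0}
"slice_counts": {"panoramic": 10, "supine_axial": 18, "supine_coronal": 9}
"slice_reduction_factors": {"supine_axial_vs_panoramic": 1.8, ...}
"breast_volume_ml": 725.33            # two 55 mm hemispheres, analytic 696.9 mL
```

The gain above 1 reflects the Biot–Savart proximity advantage of a conformal
array; the panoramic view cuts the number of tissue-bearing slices by 1.8×
versus the axial view on this phantom. Individual stages are available as
`panobreast simulate | panorama | snr | gfactor | slices`.

The library surface mirrors the CLI: `build_phantom`, `build_coil_layout`,
`loop_sensitivity`, `simulate_multicoil`, `build_panorama` /
`apply_panorama`, `pseudo_replica_snr` / `analytic_snr`, `sense_gfactor` /
`max_acceleration`, `reduction_report`, `paired_onesided_ttest`,
`required_sample_size`.

## Limitations

The phantom is piecewise-constant and noise is added in image space; absolute
in-vivo SNR levels, coil coupling, and sequence contrast are out of scope.
See `docs/methods.md` for the full model description, parameter defaults and
numerical conventions.
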