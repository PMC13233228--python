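# Methods

## The arT procedure

Atlas-based ROI analysis usually transforms measured maps into a template
space, which resamples — and therefore changes — the measured values. The
reverse-transformation (arT) pipeline implemented here goes the other way.
For each subject it takes as inputs a 4D DSC series, an anatomical
reference volume, gray-matter / white-matter / CSF probability maps, and a
nonlinear template→native displacement field (the inverse of the subject's
spatial normalisation, supplied by the user or by the phantom generator —
estimating normalisations from images is deliberately out of scope). The
stages are:

1. **Co-registration.** The time-averaged DSC series (the "mean" image,
   which carries enough anatomy for registration) is rigidly aligned with
   the anatomical reference. The estimate is computed with the DSC mean as
   the metric's fixed/sampling image — its field of view is brain-only,
   which anchors the metric far better than the air-dominated anatomical
   grid — and then inverted, so the stored transform maps DSC world
   coordinates to anatomical world coordinates. The default metric is
   Mattes mutual information (the two images are different pseudo-
   modalities); mean-squares is available for same-modality problems.
   Initialisation is centre-of-mass, optimisation a 3-level multiresolution
   regular-step gradient descent with deterministic regular sampling.
2. **Reverse ROI transformation.** The generic label map is warped through
   the displacement field onto the native anatomical grid. Each label's
   binary indicator is interpolated linearly and re-binarised at 0.5;
   competing claims go to the highest weight, ties to the lowest label id.
   Nearest-neighbour warping is avoided on purpose: it preserves values
   but produces block artifacts at curved boundaries. Fields must carry a
   `template->native` direction tag — wrong-way warps are refused rather
   than silently producing plausible-looking nonsense.
3. **Tissue filtering.** A transformed ROI keeps only voxels whose
   GM + WM probability is strictly above 10%. For the two whole-hemisphere
   ROIs the CSF probability is added to the sum, because ventricular and
   sulcal CSF legitimately belongs to a hemisphere ROI. The filter can only
   remove voxels; per-label before/after counts are reported, and a label
   losing more than 25% of its voxels is flagged as an outlier (this is how
   the phantom's CSF-flow artifact is detected).
4. **Projection to the DSC grid.** The filtered native ROIs are resampled
   through the inverse of the co-registration onto the DSC grid, again via
   indicator interpolation + 0.5 threshold. Parameter maps are never
   touched; only ROI labels move between grids.

## Perfusion parameter maps

All maps derive from the T2*-weighted signal drop of the first-pass bolus.

- **Event window.** Per slice, the drop curve `baseline − mean_signal(t)`
  (baseline = first eighth of the series) is thresholded at 10% of its peak
  drop; the contiguous run around the peak is extended outward to the
  nearest baseline crossings. A slice with no detectable drop (peak drop
  within 3× the baseline fluctuation) raises an error naming the slice.
- **TTP.** Per voxel, `TR ×` the absolute index of the deepest drop inside
  the slice window; ties break to the earliest index.
- **stdTTP.** TTP referenced to a slice-specific offset so values are
  comparable across slices. The offset is the 5th percentile of in-mask
  TTP in the slice — a robust stand-in for the earliest regular arrival.
  The exact offset definition in the originating software is not public;
  the quantile is configurable and the pipeline is validated by parameter
  recovery on the phantom rather than by matching a proprietary
  implementation. stdTTP is clamped at 0.
- **CBV.** The concentration proxy `−ln(S/S0)` (S0 = pre-window baseline
  mean) integrated over the slice window by the trapezoid rule, then
  scaled so the whole-brain in-mask mean is 1000 a.u. — an arbitrary
  reference that puts values in a clinically familiar magnitude range.
  Voxels with non-positive in-window signal become NaN and are counted.
- **Brain mask.** Otsu threshold on the mean image plus largest connected
  component.

Useful invariances, all covered by tests: stdTTP is unchanged by adding a
constant to all TTPs of a slice; CBV is unchanged by global multiplicative
scaling of the raw signal.

## The phantom generator

The generator emulates the *structure* of a perfusion study cohort, not MR
physics. A 1 mm isotropic template holds an ellipsoid-composite head with
seven labelled structures (left/right basal ganglia, pons, left/right
cerebellum, left/right cerebral hemispheres) whose volume ordering matches
real anatomy (hemispheres ≫ cerebella ≫ pons ≈ basal ganglia, with a
hemisphere-to-basal-ganglia ratio around 45). Tissue maps are derived from
the geometry (2 mm CSF rim + ventricles, cortical GM shell + deep GM +
cerebellum, WM core) and blurred by 1 mm so that partial volume gives the
10% filter real work. Defaults follow the study conditions throughout: DSC
grid 1.154 × 1.154 × 6 mm with 20 slices, 81 timepoints at TR = 0.689 s,
36 subjects, seven ROIs each (252 evaluated pairs).

Per subject (seed = master seed + subject index, so any subject is
regenerable in isolation):

- a smooth random template→native displacement field (Gaussian-smoothed
  vectors, 10 mm correlation, peak amplitude 4 mm — kept below half the
  smoothing scale so the field is invertible, which is also verified
  numerically via the Jacobian determinant; a requested non-invertible
  deformation raises an error with the measured fold count);
- the DSC series: per voxel, a gamma-variate signal dip
  `S(t) = S0 (1 − A·g(t))`, with `S0`, fractional amplitude `A`, and
  time-to-peak mixed from the voxel's tissue probabilities
  (GM: 1000 a.u., 0.35, 5.0 s; WM: 800, 0.20, 6.5 s; CSF: 1200, 0.10,
  8.0 s; shape α = 3), a smooth anterior–posterior arrival-delay gradient
  of 1.5 s across the brain, bolus arrival at 14 s, plus additive Gaussian
  noise (SD 10 a.u. ≈ 1% of GM baseline);
- a known rigid DSC→anatomy translation (uniform in ±3 mm per axis) that
  co-registration must recover;
- reference ("manual") ROIs: the warped template labels, resampled to the
  DSC grid and then perturbed by a smooth anisotropic boundary-jitter
  field. The jitter emulates raters segmenting on the coarse, low-contrast
  perfusion grid, so its scale is set in DSC-voxel units: RMS 1 mm
  in-plane and 2 mm through-plane (a third of the slice thickness), 10 mm
  correlation length. These values were chosen so that the phantom's
  manual-versus-generic disagreement lands in the range reported for human
  raters versus atlas ROIs in clinical material (Dice ≈ 0.77 for deep gray
  structures up to ≈ 0.95 for hemispheres); the jitter is a disagreement
  model, not an anatomical deformation, and is not forced to be
  diffeomorphic.

Because every curve parameter is analytic, the generator records per-ROI
ground truth: the true bolus-peak time per voxel is `arrival + delay +
mixed time-to-peak`, slice-referenced exactly like the pipeline's stdTTP
(5th-percentile offset over analytic in-brain peak times), and the true
CBV integral uses the same normalisation convention. Pipeline validation
is therefore parameter *recovery*: per-ROI mean stdTTP within one TR of
truth on noise-free phantoms, CBV rank-ordering with the generating
amplitudes, pooled bias below one TR at default noise.

An optional `artifact_csf_flow` flag corrupts the tissue maps in one
contiguous 9 mm patch near the right basal ganglia (GM/WM collapse, CSF
inflates), emulating a CSF-flow normalisation artifact; the tissue filter
then strips most of that ROI and the filter report flags it as an outlier.

### What the phantom does not emulate

No coil/EPI physics, motion, recirculation or leakage; no arteries (so the
"earliest arrival" offset comes from the fastest tissue rather than an
arterial signal, and absolute stdTTP levels sit somewhat below clinical
values); no pathological perfusion; left/right structures are symmetric.
Passing tests therefore demonstrate the pipeline's geometric and numeric
correctness and its error-propagation behaviour, not clinical performance.

## Statistics

Volume error uses the symmetric mean-normalised difference; the overlap
index is the standard Sørensen–Dice form `2|A∩B|/(|A|+|B|)`. The
surface-to-volume ratio counts exposed voxel faces (face area from the two
in-plane spacings of the face's orientation); this overestimates smooth
surfaces by up to ~50% relative to a marching-cubes estimate, which is
acceptable because SVR is used comparatively. Lin's concordance uses
population (1/n) moments; the sample-moment variant differs at O(1/n).
Bland–Altman limits of agreement are the 2.5th/97.5th percentiles of the
differences with linear-interpolation quantiles; the bias CI95 is
normal-theory `bias ± 1.96·sd/√n`. The NRMSE divides the RMS deviation of
the *fitted* values from the native values by the native mean — this is
the fit-error form, implemented as specified, so a perfectly linear but
non-identity relation (y = 2x) has zero residual around the fit yet a
large NRMSE. Differences are generic − native everywhere, and stated in
every output header. Cohort tables report median ± MAD (raw, unscaled)
per ROI plus pooled rows; per-subject VE is computed first and the median
taken afterwards.

## Numerical and design choices

- Pull-back convention throughout: fields live on the output grid and
  store world-mm offsets added to the output voxel's world coordinate;
  world space is RAS+ mm, voxel indexing 0-based, all geometry flows
  through the affine.
- Out-of-field samples fill with 0 (background); warped ROIs truncate
  silently at the field of view, with a warning when more than 10% of
  foreground volume is lost.
- The tissue-threshold comparison is strict (`>` 10%), matching
  "above the threshold" semantics; configurable.
- Field inversion (used only for verification) is fixed-point iteration
  `o_inv(x) = −o(x + o_inv(x))`, 25 iterations.
- Registration convergence: minimum step 0.01 mm (far below voxel size);
  hitting the iteration cap raises an error with the final metric value
  rather than returning a possibly unconverged transform.
- Label-map I/O: NIfTI integer volumes with a JSON sidecar carrying the
  label→name registry; displacement fields are 4D NIfTI with a JSON
  sidecar carrying the direction tag.
- Config files are JSON with all defaults emitted by `artroi init`;
  nothing is hidden in code.

## Problem sizes used in the shipped tests

Unit tests run the same world-mm geometry on coarser grids (2 mm template,
2.3 mm in-plane DSC) — enough spatial detail for contract and property
tests at a fraction of the cost. Study-condition checks (default grids,
36 subjects) run once in the acceptance suite and in
`scripts/acceptance.py`; parameter recovery uses 8 noise-free subjects at
full resolution.

## Known limitations

- Co-registration is rigid only; affine/deformable DSC↔anatomy alignment
  is out of scope.
- The stdTTP slice offset is a quantile heuristic; absolute stdTTP values
  depend on it, differences between tissues much less so.
- CBV is a non-deconvolved first-pass integral in arbitrary units — no
  CBF/MTT, no arterial input function, no leakage correction.
- The outlier flag is a fixed removed-fraction threshold, not a statistical
  test across the cohort.
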