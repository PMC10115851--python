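# Methods

## The problem

Skull stripping (brain extraction) removes every non-brain tissue from a
head MRI, leaving the parenchyma for downstream quantification.  Tools
tuned to human anatomy fail on dogs and cats, whose brains are ringed by
massive masticatory muscle, thick bone and poorly contrasted boundaries.
This package implements an atlas-based pipeline for animal MRI: a
species brain atlas — an intensity template plus a binary brain mask —
is registered onto the subject and its mask is transferred.  Because the
atlas contains only the brain while the subject contains the whole head,
this is *model-to-image* registration: the brain is the only content the
two images share, which shapes nearly every design choice below.

## Pipeline

1. **Geometry transposition** (`core.transpose_geometry`).  The atlas is
   resampled (linear interpolation; nearest-neighbor for the mask) onto a
   grid with the target's voxel spacing, matrix size and axis
   orientation, then re-labelled into the target frame so it sits at the
   center of the target field of view.  All geometry uses the LPS
   convention internally; NIfTI RAS affines are converted on read/write.
2. **Histogram matching** (`intensity.histogram_match`).  The template's
   intensity distribution is remapped to the target's by a monotone
   piecewise-linear map aligning 7 quantile landmarks estimated from
   1024-bin histograms.  Background is *included* in the histograms: for
   a skull-stripped template the above-mean histogram holds brain tissue
   only, while the target's holds every head tissue, so excluding
   background mismatches the landmark sets and compresses the template
   into the top of the target's range (measured: median rigid rotation
   error grows from ~1.4° to ~6°).  With full histograms the dark
   background pins the lower landmarks and the map stays gentle.
3. **Brain localization** (`locator`).  Felzenszwalb–Huttenlocher graph
   segmentation of the target's central slice with scale
   `k = 200 · S_atlas`, where `S_atlas` counts non-background template
   pixels on the resampled atlas' central slice.  Because `k` scales
   with pixel counts, the segmentation (and hence the localization) is
   invariant to in-plane resolution.  The slice is first rescaled so its
   99.5th percentile sits at 255: the scikit-image implementation
   divides the scale by 255 (a convention from 8-bit reference data),
   and the rescaling makes the published factor intensity-scale-free.
   Candidate regions are filtered to plausible brain areas
   (0.5–4 × `S_atlas`) and above air-level intensity; among candidates,
   the one whose centroid is closest to the plane's reference point
   (defaults: slice center; shifted 10 % dorsally for sagittal slices)
   is selected, and the atlas is translated in-plane onto its centroid.
   The acquisition plane is detected from the geometry: the stacking
   index axis (largest spacing, ties toward the last axis) is matched to
   the physical axis it is most aligned with (x ↔ sagittal, y ↔ dorsal,
   z ↔ transverse).
4. **Rigid registration** (`registration.register_rigid`).  Negated
   Mattes mutual information (50 bins, B-spline interpolation of the
   moving image) restricted to the atlas brain mask dilated by a
   10-voxel ball, optimized over a 3D Euler rotation + translation.
   The optimizer is a step-controlled gradient descent (initial step 1,
   step halving factor 0.6 on direction reversal, minimum step 1e-6, 50
   iterations).  Two scaling choices matter: the fixed image is cropped
   to the dilated-mask bounding box, and rotation parameters are
   rescaled by the intensity-weighted mean squared radius of the moving
   template — physical-shift scaling computed over the *brain* rather
   than the image corners.  Without this, rotation steps are ~50× too
   small and the stated iteration budget leaves rotation essentially
   unmoved.  Translation is initialized by matching the intensity
   centroid of the masked target region to the template's centroid
   (moments initialization), which supplies the through-plane component
   the 2D localization cannot observe.
5. **Elastic registration** (`registration.register_elastic`).  Cubic
   B-spline free-form deformation with a control point every 8 voxels
   (every voxel for thick-slice 2D-type series, detected when slice
   thickness exceeds twice the in-plane spacing), optimized with
   L-BFGS-B (gradient tolerance 1e-5, 15 iterations) on the same masked
   metric, mask dilation 10 voxels (1 for 2D-type).  Control-point
   displacements are box-bounded at ±0.8 mm: in model-to-image
   registration an unbounded FFD *balloons* — MI increases when each
   non-brain head tissue is paired with a distinct atlas tissue instead
   of all collapsing onto atlas background — and the bound is the
   package's explicit deformation prior (cubic-spline superposition
   still yields ~2 mm of boundary motion).  The metric uses a seeded
   25 % random sample of the masked voxels; when L-BFGS-B aborts its
   line search far from convergence, optimization resumes from the
   current coefficients with a freshly drawn (deterministically seeded)
   sample set, which perturbs the cost surface enough to get unstuck.
6. **Mask extraction** (`extraction`).  The atlas mask is transported
   through the composed transform with linear interpolation,
   thresholded at 0.5, reduced to its largest connected component,
   holes of ≤ 27 voxels filled, and multiplied voxelwise into the
   target to produce the skull-stripped image.

## Validation metrics

With A the automatic mask, M the reference mask and V the voxel count:
Dice `2|A∩M|/(|A|+|M|)`, Jaccard `|A∩M|/|A∪M|`, sensitivity `|A∩M|/|M|`,
specificity `(V−|A∪M|)/(V−|M|)`.  All are computed with integer counts
until the final division; `J = D/(2−D)` exactly.  Cohort summaries
report mean ± sample (n−1) standard deviation; cases on which a metric
is undefined (e.g. both masks empty) raise rather than silently
defaulting, and are excluded from aggregates with an error count.
Specificity is near 1 whenever the brain is a small fraction of the
image — use it comparatively, not as an absolute score.

## Tissue segmentation

After extraction, a plain K-means (K = 3, k-means++ with fixed seed,
tolerance 1e-6, ≤ 300 iterations) on the masked pixel intensities of a
chosen slice separates CSF, gray and white matter.  Clusters are mapped
to tissue names by sorting cluster centers under the declared contrast
convention (T1-like: CSF darkest, white brightest; T2-like reversed).
Relabelling by center order makes the output invariant to the
initialization's label permutation.  Intensity is the only feature; no
spatial regularization or partial-volume model is used, so voxels mixed
by the point-spread function (thin ventricles especially) are the
dominant error source.

## The synthetic phantom

No public animal cohort accompanies the method, so validation runs on a
cranial phantom with analytic ground truth (`phantom`):

- **Brain**: an ellipsoid (default semi-axes 10 × 13 × 9 mm — a small
  cat-scale brain that leaves room for 25 mm displacements in a
  64³ field of view) containing deliberately *asymmetric* internal
  anatomy: two lateral and one posterior white-matter lobes and a
  dorsally offset, elongated CSF ventricle.  With concentric
  constant-intensity shells the pose is near-unidentifiable to any
  intensity metric (the MI at the true pose measured *worse* than at a
  grid-aligned wrong pose); asymmetric high-contrast structure is what
  real brains have and what makes registration well-posed.
- **Texture**: a fixed field of 120 Gaussian blobs (widths 0.06–0.30 of
  the brain radius, amplitude ±25 %) defined in normalized brain
  coordinates, so it rotates, translates and inflates with the brain.
  It stands in for gyral/sulcal intensity structure and gives the
  metric sub-degree rotation sensitivity.
- **Head tissues**: a CSF-filled gap (1 mm), dark skull shell (2.4 mm),
  bright scalp/fat layer (1.8 mm) and two lateral muscle blobs.  The
  scalp layer matters: without it the skull–air boundary gradient is
  ~3 noise standard deviations under the PSF and graph segmentation
  cannot hold the head/background boundary.
- **Contrast regimes**: T1-like (CSF < gray < white), T2-like
  (white < gray < CSF) and FLAIR-like (CSF < white < gray) intensity
  orderings, with regime-appropriate skull/muscle/scalp values.
- **Acquisition**: the analytic scene is sampled at voxel centers on a
  grid of arbitrary orientation (sagittal/dorsal/transverse realized as
  axis-permutation direction matrices), blurred with a Gaussian PSF of
  0.6 voxel (partial volume; configurable), and degraded with additive Gaussian
  noise (2 % of the regime's maximum intensity).  Rician noise, bias
  fields and k-space artifacts are out of scope.
- **Atlas**: the same brain rendered unposed, noise-free and
  skull-stripped on its own 0.9 mm isotropic native grid — like a real
  published template, and deliberately incommensurate with the subject
  grid so the atlas is genuinely resampled (identical grids produce a
  spurious MI reward for grid-aligned poses).
- **Truth**: brain mask and tissue labels are evaluated analytically
  from the generating geometry, never by running the pipeline.

Default study conditions: 64³ voxels, 1.25 mm in-plane / 2.0 mm slices
for extraction studies (isotropic 1.25 mm for rigid-recovery studies,
the 3D-acquisition regime where sub-degree rotation comparisons are
meaningful); poses up to 15 mm translation and 10° rotation; brain
inflation 1.04–1.10 emulating inter-subject size variability.

What passing phantom tests do **not** show: performance on real cohorts
with breed-specific cranial shapes, pathology, bias fields, or atlases
built from different populations.  The phantom establishes that the
pipeline's machinery — localization, masked MI optimization, bounded
FFD, mask transport — recovers known geometry under controlled
difficulty, not clinical accuracy.

## Numerical choices and degenerate inputs

- Voxel centers define physical positions; resampling fills
  out-of-support voxels with 0 (the atlas background value).
- Central slice of an even-sized axis: the lower middle index.
- Felzenszwalb ties are resolved by the implementation's stable edge
  ordering; two runs on identical input give identical label images.
- Equidistant centroid candidates resolve to the smaller label.
- Masks transported with linear interpolation binarize at ≥ 0.5.
- Both registration stages re-evaluate the metric at their
  initialization and return the initialization if optimization ended
  worse, so a stage can never actively harm the alignment it received.
- Constant images are rejected by histogram matching; masks that are
  empty where foreground is required raise typed errors
  (`vibe.errors`) that the CLI maps to exit codes 2 (input) and
  3 (pipeline stage).

## Known limitations

- The elastic displacement bound (±0.8 mm) is tuned to modest
  inter-subject variability; grossly different brain shapes need a
  larger bound (config `elastic.displacement_bound_mm`) and accept more
  ballooning risk.
- Rigid recovery is quoted for the isotropic 3D regime; thick-slice
  series quantize the through-plane axis too coarsely for sub-degree
  rotation accuracy.
- K-means tissue segmentation degrades wherever partial volume mixes
  classes; the phantom quantifies this (per-class Dice drops from ~1.0
  to ~0.4 on a 2-pixel-wide ventricle when the PSF is enabled).
- Localization assumes the brain is visible on the central slice; very
  off-center or cropped acquisitions need the `--reference-point`
  override.
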