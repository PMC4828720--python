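# Methods

`smart3d` quantifies the spatial organisation of brain-metastasis
microenvironments in tissue-cleared, multi-channel 3D fluorescence volumes:
which voxels are tumor (K8), astrocyte (GFAP), proliferating nucleus (EdU)
or vessel; how those classes arrange themselves around each metastasis; and
what the resulting per-tumor indices look like statistically. This note
records the models, the parameters that matter, and the design choices made
where the problem left them open.

## Conventions

Volumes are arrays indexed `(x, y, z)` with `z` the optical-section axis;
voxel spacing `(sx, sy, sz)` is in μm and may be anisotropic. All public
distances are Euclidean in physical μm (the distance transform uses the
spacing as sampling), all volumes are in μm³, and a voxel's position is its
center. Connectivity for component formation defaults to 26 (the most
permissive) and is configurable wherever components are formed.

## Background removal

Cleared tissue carries a strong, spatially inhomogeneous autofluorescence
field. The estimator has four stages:

1. **Rough estimate** — a per-voxel percentile filter over a cubic window.
   The window edge follows the smallest-object rule: 1.25× the diameter of
   the smallest bright object, rounded up to odd (`window_edge_for_object`).
   With ~6 μm nuclei and vessels at 1 μm pitch this gives edge 9. An object
   that fills its own window contaminates the estimate beneath it, which is
   why the window must exceed the smallest object and why larger objects are
   handled by stage 2. The percentile defaults to 20: under sparse bright
   foreground a low order statistic tracks the background. Borders use
   clipped (shrunken) windows; percentiles interpolate linearly between
   order statistics.
2. **Error detection** — the rough field is wrong where objects are larger
   than the window. The volume is tiled into blocks (default: the window
   edge, so errors align with the filtering scale); per block five summary
   features (mean and variance of the rough field, gradient magnitude of the
   block-mean field, fraction of voxels above the field, mean residual) are
   standardised robustly across blocks and scored by a one-class SVM
   (ν = contamination, default 0.05, RBF γ = 0.02). Standardising across
   blocks makes the flags invariant to global intensity offsets. γ is fixed
   small because with only tens of blocks a per-dataset bandwidth overfits
   and flags far more than the ν fraction. ν caps the flagged fraction, so
   contamination should be set at or above the expected fraction of
   over-window blocks.
3. **Re-estimation** — voxels in flagged blocks are replaced by
   inverse-distance-squared interpolation of the unflagged blocks' means.
4. **Subtraction** — `max(volume − refined − offset, 0)` where
   `offset = median(volume − refined)`. A q-percentile window statistic sits
   roughly the q-quantile of the noise *below* the background level; the
   median residual (robust to sparse bright foreground) estimates that
   offset so the subtraction is unbiased for the background level itself.
   Structures thinner than the window keep their net intensity.

## Voxel classification

Per channel and per scale σ ∈ {1, 2, 4} μm (configurable; a single scale
reproduces the minimal 8-feature-per-channel vector), the volume is
Gaussian-smoothed (σ converted to voxels per axis) and four families are
computed in physical units: intensity, gradient magnitude, the three Hessian
eigenvalues and the three structure-tensor eigenvalues, each triple sorted
descending — 8 features per channel per scale. Derivative kernels use a 6σ
support so they sum to ~0 on constants. Concatenating channels gives the
multi-channel feature vector (MFV); no normalisation is applied (forests
are scale-tolerant).

One binary random forest per foreground class — tumor, astrocyte,
proliferating, vessel — with 200 trees and 2 candidate features per split,
seeded and single-threaded for reproducibility. A voxel is positive when
the majority vote (class probability) reaches 0.5; prediction runs in flat
tiles, which cannot change any prediction because voxels are independent.
Positive predictions of different classes may overlap: the classes are
independent stains. Accuracy is summarised by stratified 10-fold
cross-validated F1 computed from pooled out-of-fold confusion counts.

**Structural segmentation.** Connected components of the tumor mask with
physical volume above a user-chosen threshold become tumor clusters; any
component containing at least one epithelial (K8) voxel is kept regardless
of size. The threshold is an expert decision; a helper reports the
component-volume spectrum to guide it.

## Spatial quantification

All inputs here are voxel-classified masks, not raw intensities.

* **Proliferative index** = |EdU ∩ cluster| / |cluster| (voxel volumes
  cancel).
* **Surrounding space** at distance *dis* = spherical dilation by *dis*
  minus the cluster, computed as a threshold of the anisotropy-aware
  distance transform (exact on anisotropic grids, unlike discrete
  structuring elements). **Gliosis index** = astrocyte fraction of the
  24 μm shell — 24 μm being the spatial size of one astrocyte, so the shell
  surveys the first astrocyte layer.
* **Concentric zones** of thickness t (default 10 μm): inward zone *i*
  holds cluster voxels whose distance to the cluster's complement lies in
  ((i−1)t, it]; a voxel touching the exterior is in zone 1 and the zones
  partition the cluster. Outward zones bin the exterior distance field up
  to a required maximum extent. **Zone profiles** are per-zone feature
  volume fractions; empty zones yield NaN, never 0, so conservation
  (Σ profile·|zone| = |feature ∩ cluster|) holds exactly over non-empty
  zones.
* **Tumor-to-vessel distances**: the vessel mask's distance transform
  sampled at cluster voxels — contract-identical to per-voxel
  nearest-neighbour search but linear-time; the distribution is summarised
  by the mode of a Gaussian KDE (Scott bandwidth, 1 μm evaluation grid).
* **Mean vascular density**: vessel volume fraction inside the cluster and
  in the peritumoral shell (within 100 μm of the surface).

## Statistics

Per-tumor observations (log₁₀ volume in μm³, proliferative index, gliosis
index) feed: size classification (large ⇔ log₁₀V > 5.0; small/medium cutoff
4.5, config-exposed; boundaries belong to the lower class); Gaussian KDE by
size class (hand-written equal-weight Normal mixture with explicit or
Scott bandwidth — the explicit-bandwidth single-observation case is part of
the contract); quadratic regression of proliferative index on log₁₀ volume
with a two-sided t-test on the curvature (p is NaN for an exactly
interpolating fit) and vertex −b/2a; a two-sided variance F-test
(2·min(tail, 1−tail)); and Pearson correlation of proliferative index with
√gliosis (square root as variance stabiliser for small fractions), per
size class.

## Synthetic phantoms

The generator emulates the study scenes: lobular tumors (unions of
overlapping spheres; an optional co-option mode chains lobes along a vessel
centerline), tortuous vessels (tubes around random walks), astrocyte caps
covering an exact fraction of each tumor's 24 μm shell (a coherent angular
sector — coverage of real tumors is not spatially uniform), EdU nuclei
placed per zone to a target proliferative fraction, scattered nuclei, a
sum-of-Gaussians background, and Poisson-scaled plus Gaussian noise.
Defaults: 72³ voxels at 1 μm pitch, two tumors of radius 9–12 μm with three
lobes, three vessels of radius 3 μm, coverage 0.40, proliferative target
0.15, channel amplitude 180, background amplitude 30, Gaussian σ 3,
Poisson scale 1, PSF σ 1 μm. Everything is seeded and deterministic.

Two fidelity rules matter:

* **Partial-volume rendering.** Channels are rendered from antialiased
  indicators whose coverage ramps across one voxel and crosses ½ exactly at
  the analytic surface, so thresholding the clean scene at half amplitude
  reproduces the digital truth mask. Binary indicators would inflate every
  object's apparent surface by ~half a voxel and bias any downstream
  segmentation outward. The astrocyte cap, a voxel-exact set, ramps with
  its interior distance instead.
* **Exact targets.** Astro caps contain exactly the requested fraction of
  shell voxels (painted only in each tumor's exclusive shell region, with
  tumor placement keeping other tumors out of every shell). EdU uses whole
  nuclei whose radius shrinks toward the remaining gap, landing within
  ±0.02 of the target for clusters ≥1000 voxels. Stored per-tumor truths
  are recomputed from the masks, so they match mask-derived values to
  machine precision.

`sample_training_labels` stands in for expert annotation: a third of the
label budget is foreground, two thirds background with 60% of it within
3 μm of the object. An even class split would inflate the foreground prior
far above its true prevalence and starve the forest of halo examples; both
push the decision surface outward, which matters most for high-surface
classes (tubes).

What the phantoms do *not* model: depth-dependent attenuation and
scattering, anisotropic PSFs, stain cross-talk, deformable tissue motion,
real astrocyte morphology (caps are solid sectors, processes are straight
filaments). Passing on phantoms therefore certifies the geometry,
estimation and calibration machinery, not performance on any particular
microscope's data.

## I/O and alignment

Stacks are multi-page TIFFs (pages = z-planes of (y, x)); masks are 8-bit,
labels 16/32-bit, floats 32-bit; spacing travels in the config, not the
TIFF. Consecutive z-planes can be realigned by exhaustive integer-shift
search minimising the MSE over the full overlap (ties to the smaller shift
magnitude, then lexicographic), with cumulative shifts applied and
zero-fill at the edges. Rotation/scaling and multi-tile stitching are out
of scope. Every CLI command writes a provenance record (config hash, seed,
version).

## Validation experiment sizes

The validation suite (also run by `scripts/acceptance.py`) uses problem
sizes chosen to exercise each property at desk scale: 50 random instances
per geometric primitive (grids ≤ 20³–32³, mixed spacings) against
brute-force references; a 48³ single-tumor scene for zone conservation; a
64³ four-class scene with a 1% label budget for classifier fidelity; a 48³
filament scene for background recovery; the default 72³ scene end-to-end
for parameter recovery; 1000 null replicates for test calibration; 100
seeded stacks for alignment. The brute-force references use direct
nearest-neighbour search (all-pairs, or a k-d tree query above 2·10⁷
pairs) and per-voxel window extraction, independent of the implementation
paths they check.

## Known limitations

* ν-SVM error detection cannot flag more than ~ν of the blocks; scenes
  where over-window objects cover more than the contamination fraction need
  a higher contamination setting.
* The volume threshold for structural segmentation and the expert label
  budget are irreducibly user choices; defaults here are phantom-scaled.
* KDE modes are grid-argmax values (1 μm grid for distances), not
  continuous optimisers.
* Inward zone depth is measured to the in-grid complement; a cluster
  touching the volume border has no "exterior" there, so its border face is
  treated as interior.
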