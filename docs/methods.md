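# Methods

This note documents the models and numerical choices behind `photorecon`:
what is computed, under which assumptions, and where the design was genuinely
open.

## Problem setting

Brain banks routinely photograph coronal slices of dissected specimens before
histology. Those photographs carry quantitative information — regional
volumes, atrophy patterns — that is lost unless the 2D slices can be put back
together in 3D. `photorecon` implements that pipeline on synthetic data:
planar calibration of the photographs, joint slice-to-volume reconstruction
against a 3D shape reference, a digital-slicing simulator with ground truth
for error quantification, a label-conditioned generative model for
domain-randomized segmentation training data, and the group/validation
statistics used for volumetry studies.

## Photograph preprocessing

**Fiducial detection.** Markers of known physical geometry are located by
SIFT keypoint matching (scikit-image's SIFT) between small marker templates
and the photograph: Lowe-ratio matching (ratio 0.75, cross-checked), a
RANSAC-fitted similarity transform per marker, and the template's reference
point mapped through that transform. A marker needs at least 4 consistent
matches; markers closer than half a template diagonal are reported as
ambiguous. Marker appearance is a user input (any textured patch works); the
synthetic test scenes use smoothed-noise patches.

**Calibration.** The point count forces the model: 4 rectangle corners give
an exact (DLT) projective homography from raw pixels to physical mm; 3
ruler-arm points give an affine map sending the two arms to orthogonal mm
axes (residual perspective is accepted); 2 points give isotropic scaling
only, `pixel_size = known_distance / pixel_distance`. Coordinates are
(row, col) with origin at the top-left pixel center; physical units are mm.

**Rectification** resamples onto a regular grid of the target pixel size by
linear interpolation (zero fill outside the footprint). Color is reduced to
grayscale with luminance weights (0.299, 0.587, 0.114) — downstream
processing is intensity-based and grayscale has proven more robust than RGB
for this material.

**Segmentation** is thresholding (Otsu by default) followed by morphological
open-then-close with a 1 mm disk and removal of components under 20 mm²;
components are labeled with 8-connectivity. Interior holes are kept as
morphology produces them. Externally edited masks can be supplied instead.
Slice ordering and the grouping of connected components into anatomical
slices (e.g. a separated temporal pole) come from a declarative JSON spec
rather than an interactive tool, which keeps the pipeline headless and
testable.

## Joint slice-to-volume reconstruction

Given N slices (image S_n, mask M_n), a nominal thickness t, and a reference
volume R (binary surface-scan rasterization, or a probabilistic atlas), the
unknowns are per-slice planar transforms Phi_n, a global anterior-posterior
scale s, and a reference pose Psi. They maximize

    F = alpha * D(M, R o Psi)
      + beta  * (1/(N-1)) sum_n C(S_n, S_{n+1})
      + gamma * (1/(N-1)) sum_n D(M_n, M_{n+1})
      - nu    * (1/N) sum_n |log det Phi_n|

with D the soft Dice overlap `2*sum(ab)/(sum a + sum b + eps)` (eps = 1e-6 in
the denominator only, so that two empty masks give 0 rather than 1), C a
normalized cross-correlation, and the last term an area-change penalty that
keeps slices from shrinking or shearing (important for nearly-empty end
slices). Default weights: surface mode alpha=.95, beta=gamma=.025,
nu=gamma/100; atlas mode alpha=.8, beta=gamma=nu=.1. The reconstruction is
insensitive to the exact values.

**Search spaces.** Surface mode: full 2D affine Phi_n (6 dof,
parameterized as translation + rotation + log-scales + shear so the
determinant stays positive), free s = exp(sigma) > 0, rigid Psi (Euler
angles + translation). Atlas mode: rigid Phi_n (3 dof, which makes the
regularizer identically zero), s fixed at exactly 1, and a full 3D affine
Psi — the atlas cannot correct specimen-specific shape, so the slices are
trusted more and the reference less.

**Discretization.** The objective is evaluated on the assembled slab grid:
each slice is pulled through Phi_n onto a common in-plane grid (padded to
1.2x the largest slice bounding box, centered on the world origin), and slab
n sits at z = (n - (N-1)/2) * s * t. The reference is pulled through Psi onto
that same grid by trilinear interpolation. The beta/gamma sums compare
consecutive slabs on the grid. The NCC support is the soft union of the two
slice masks (as multiplicative weights), so background never dominates the
similarity and the term stays differentiable.

**Optimization.** F is maximized by running L-BFGS (scipy's L-BFGS-B,
history 10, up to 500 iterations, ftol 1e-9) on -F with *analytic*
gradients: the bilinear/trilinear samplers in `_interp.py` return exact
derivatives with respect to the sampling coordinates, which are chained
through the transform parameters by hand (the code is plain numpy
reverse-mode for this shallow computation graph). A finite-difference check
on a small fixture agrees to better than 1e-4 relative error. Initialization
stacks the slices with their mask centroids at in-plane (0,0), s = 1, and
matches the reference centroid to the stack centroid. A 2-level
coarse-to-fine pyramid (2x block averaging) is on by default to enlarge the
convergence basin; the reported objective trace is from the full-resolution
level and is monotone by construction of the line search.

**Surface rasterization.** Meshes are checked for watertightness (trimesh),
hole-filled if needed, and filled by scanline parity counting: a voxel is
foreground iff its center lies inside the surface, determined by counting
triangle crossings along the z axis below each voxel center (vectorized per
triangle; grid columns carry a tiny irrational offset to dodge edge
degeneracies). Analytic volumes of a cube and an icosphere are reproduced to
within 5% and 2% respectively at the tested resolutions.

**Output.** The reconstructed volume keeps the photographs' in-plane pixel
size and an anterior-posterior spacing of s * t (voxels are deliberately
anisotropic); the NIfTI affine maps image rows to the inferior-superior axis
(photographs are assumed upright) and slab index to posterior-anterior.

## Digital slicing simulator

The simulator cuts an isotropic volume into a photo-like stack every S
voxels. With thickness jitter j (in slice units), slice n is extracted at an
integer index drawn uniformly from [nS - jS, nS + jS]. Each slice receives
an independent random planar affine (defaults +-5 mm translation, +-10 deg
rotation, +-0.1 log-scale/shear — the magnitudes are a package choice, as
only relative error trends are meaningful) and a multiplicative illumination
field exp(g), g a smoothed Gaussian field scaled so max|g| equals the
configured amplitude. All ground-truth poses are recorded.

**Error metric.** Reconstruction error is the mean displacement over all
foreground voxels between the recovered and true pose of every slice, in mm,
after an optimal global rigid alignment (Kabsch) that removes the irrelevant
common pose of the two stacks.

**Phantom.** The default phantom is a 64^3 volume at 0.7 mm: a cortex-shell
ellipsoid, inner white matter, a ventricle and four deep-gray blobs, cut to
a single hemisphere (the cut makes in-plane cross-sections asymmetric, which
removes rotational ambiguity that a pure ellipsoid would have). Intensities
are per-label base values plus smooth noise. It emulates the geometry and
contrast structure of an isotropic MRI hemisphere scan, not its anatomy:
passing tests show the algorithms recover known distortions under realistic
shape/contrast conditions, not that they handle real tissue appearance,
cutting artifacts, or real surface-scan noise.

## Generative process for segmentation training data

`simulate_training_pair` implements domain randomization conditioned on a 3D
label map: (1) a smooth random 3D deformation (amplitude-bounded, built from
upsampled low-resolution noise) plus an independent small planar jitter per
coronal slab, simulating imperfect 3D reconstruction; (2) per-label
univariate Gaussian intensities with means and variances drawn fresh every
call — univariate because grayscale outperforms RGB modeling for this
material; (3) digital slicing at a thickness drawn from a configured range,
with small per-slice variations around it (box-window partial-volume
averaging along the slicing axis); (4) per-slice multiplicative bias field
and brightness/contrast/gamma transform `I -> clip(c*I + b)^gamma`; (5)
resampling back to the isotropic output resolution. The target is the
deformed label map on the same grid. All draws are reproducible bitwise
given a seed.

## Evaluation statistics

2D Dice is computed per label on selected slices; a label absent from both
rasters is undefined (NaN), never 0 or 1. Label volumes are voxel counts
times voxel volume. Group comparisons residualize volumes on [1, age, sex]
by OLS (pooled fit over both groups) and report AUROC — the normalized
Mann-Whitney U, with mid-ranks for ties — and a two-sided Wilcoxon rank-sum
p (exact enumeration when the smaller group has <= 8 and combined n <= 16,
normal approximation with tie correction otherwise). No multiple-testing
correction is applied by default (a Bonferroni option exists). Contralateral
volumes are averaged when both hemispheres are available. Accumbens area and
ventral diencephalon are excluded from group statistics by default — their
photographic contrast does not support reliable segmentation. Validation
correlations against reference volumetry use Pearson's r; two methods
validated against the same reference sample are compared with Steiger's Z
for dependent correlations (Fisher z-transforms with the shared-sample
covariance term).

## Known limitations

* Per-slice transforms are affine only; nonlinear slice deformation is out
  of scope (it creates large solution ambiguities for this objective).
* The optimizer is local: pathological initial poses (rotations well beyond
  the tested +-10 deg) may not be recovered despite the pyramid.
* Gradients assume linear interpolation; mask-boundary voxels carry all the
  Dice gradient, so very coarse grids can stall.
* The phantom's simplicity means absolute error numbers are optimistic;
  only trends and recovery properties transfer to real material.
* Segmentation networks themselves (training and inference) are out of
  scope; the generator's outputs are network-agnostic.

## Problem sizes used in tests

The test suite and acceptance script run on the 64^3 phantom (0.7 mm): the
slice-spacing/jitter trend uses 10 random seeds at S=8 and 3 at S=2/16;
recovery experiments use S=4 (13 slices). These sizes were chosen as the
smallest at which the geometric effects of interest (scale drift, jitter
degradation) are well resolved.
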