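# Methods

## Problem and model

The package classifies a segmented pulmonary nodule as adenocarcinoma-like
vs granuloma-like from a linear-SVM score over a small set of radiomic and
vascular features. The working hypothesis it operationalizes: malignant
nodules remodel their local vasculature, so the vessels attached to a
malignant nodule are more numerous and more tortuous (higher centerline
curvature) than those attached to a benign granuloma, while the nodule
interior is texturally more heterogeneous. Four features carry the primary
signal (`FS_nv`): the dispersion of GLCM correlation across 3D directions,
the kurtosis of pooled diagonal-gradient responses, the pooled mean
centerline curvature of attached vessels, and the attached-vessel count.

## Segmentation

Region growing takes the 26-connected component of the HU window
[−600, 200] containing the seed, inside an ROI of half-extent 25 mm. The
window covers solid, part-solid and non-solid nodules plus non-contrast
vessels while excluding aerated lung (≈ −900 HU). Vessel separation opens
the grown mask with a spherical element of radius 2 mm rasterized in
physical units (so 1–5 mm slice thicknesses behave consistently), keeps the
largest surviving component as the nodule body, closes it with the same
element, and reclaims a one-voxel boundary layer by 26-dilation clipped to
the grown mask — a round element cannot reproduce the staircase shell of a
digital boundary, and without this step the residual shell fragments into
spurious "vessel" components and costs several Dice points on small
nodules. Residual components adjacent (26-connectivity) to the nodule and
larger than 2 mm³ are the attached vessels; smaller residues are treated as
opening debris (shaved spiculations). Nodules whose principal-axis ratio
exceeds 3 trigger an elongation warning: a vessel thicker than the opening
radius has likely stayed fused — the documented failure mode of
morphological separation.

The parameters live in `RGParams` and are tunable; the defaults are the
package's choices, since only the algorithm class (threshold region growing
plus morphological separation) is fixed by the problem.

## Texture bank (830 features)

The bank is a versioned manifest (hash exposed as `bank_version`) of seven
families: 22 first-order statistics of in-mask HU; 448 GLCM/Haralick
features (14 statistics × 13 unique distance-1 3D directions plus
mean/std/range aggregates across directions, at displacements 1 and 2);
96 gradient features (12 statistics over 8 response images: three
spacing-corrected axis gradients, gradient magnitude, the two axial-plane
diagonal difference kernels, their pooled responses, and a Laplacian);
60 + 60 + 48 multi-scale features (Laplacian-of-Gaussian and Gaussian at
σ = 1…5 mm, difference-of-Gaussian between adjacent scales); and 96
single-level `haar` wavelet features (12 statistics × 8 subbands, mask
decimated to the subband grid). Quantization is equal-width with Ng = 32
over the in-mask range, upper-edge inclusive.

Two members have first-class names because the classifier uses them:

* `correlation_std` — population standard deviation of the Haralick
  correlation over the 13 distance-1 directions: a texture-anisotropy
  measure (0 for direction-independent texture).
* `diagonal_gradient_kurtosis` — Pearson kurtosis (normal = 3) of the
  responses of the four ±45°/±135° axial diagonal difference kernels pooled
  over in-mask voxels; heavy-tailed (impulse-like) texture raises it.

Degenerate inputs (constant regions, empty GLCM pairs) emit sentinel 0
values with per-feature flags; the vector length is invariant by contract
because downstream classifiers need fixed-width tables.

## Shape (13) and sharpness (12)

Shape descriptors come from a marching-cubes mesh of the mask, pre-smoothed
with a 0.8-voxel Gaussian: raw binary meshes overestimate a sphere's
surface by ~9% through staircase facets, which would bias sphericity to
≈ 0.92 for a perfect digital sphere. Sphericity is π^{1/3}(6V)^{2/3}/A with
voxel-counted V and mesh A; convexity is mesh volume over convex-hull
volume (bounded by 1 by construction); roughness is the coefficient of
variation of the surface radial distance from the centroid. The radial-CV
definition was chosen over a surface-to-hull area ratio because the latter
is not monotone in spiculation at nodule scale — the hull area over spike
tips inflates faster than the mesh area, so A/A_hull *decreases* for a
sphere with eight 30%-amplitude spicules — whereas radial dispersion grows
with both spicule count and amplitude. The remaining ten descriptors are
standard (volume, area, surface-to-volume, equivalent and maximum 3D
diameter, PCA axis lengths, elongation, flatness, compactness).

Sharpness samples the Gaussian-derivative gradient magnitude (σ = 1 mm) on
the one-voxel surface shell: nine statistics at the base scale plus the
mean at window scales 0.5, 2 and 4 mm. A uniform volume yields all-zero
gradients with flags.

## Vessel tortuosity

Each labeled vessel component is skeletonized (3D medial-axis thinning);
the skeleton voxel graph (26-connectivity) is split into branches at
junction voxels (degree ≥ 3), cycles are broken at one edge, and each
branch is mapped to mm coordinates and smoothed with a Gaussian of σ = 2
points before differentiation. σ = 2 rather than 1 because voxel-chain
jaggedness at σ = 1 leaves ~15% positive curvature bias on noise-free
helical phantoms; at σ = 2 the end-to-end error is ~5% on average.
Branches with fewer than 5 points or shorter than 3 mm after smoothing are
dropped: the first have undefined derivative stencils, and the second are
junction spurs that collapse under smoothing into near-degenerate polylines
whose spurious curvature (> 10 mm⁻¹) would dominate pooled statistics.

Curvature and torsion are central differences with respect to arc length;
the three points at each branch end are excluded (the third derivative
reaches three stencils deep). Torsion is zeroed where |r′×r″| is below
tolerance (locally straight). The distance metric is arc/chord (≥ 1);
near-closed branches (chord < 1 µm) are excluded from the mean with a log
entry. Fractal dimension is box counting over ≥ 5 geometric scales between
2× point spacing and half the branch extent, with the curve densely
resampled and counts averaged over four grid phases to damp grid-phase and
orientation dependence (rotation changes the estimate by < 0.05).

Case-level block: `curvature_mean` pools κ over all points of all branches
(long vessels weigh proportionally; the per-branch-mean alternative is one
flag away), fractal-dimension and distance-metric means are per-branch
means, and `n_attached_vessels` comes from the segmentation. Two auxiliary
comparison features serve the `FS_v` set: the maximum over branches of the
per-branch maximum curvature, and the 4th of 10 equal-width bins of |τ|
over [0, 0.5] mm⁻¹ (1-based, i.e. (0.15, 0.20] mm⁻¹), as a proportion of
pooled points. These two are not part of the 859 core features — they
belong to a separate comparison feature family — and ride along as extra
columns so the feature-set registry can resolve them.

## Classifier and selection

Linear SVM, C = 1, no class weighting (the design is balanced 22/22).
Stratified threefold CV with a fixed default fold seed (20210309, surfaced
in results); features are z-scored with statistics fitted on training folds
only. The single reported AUC pools held-out decision scores across folds
into one ROC (per-fold AUCs are retained); AUC itself is the Mann–Whitney
rank statistic with midrank ties, identical to the trapezoidal ROC area.
Fold assignment is made invariant to row order by canonically sorting case
ids before splitting. Forward selection greedily adds the feature
maximizing the same CV AUC with the same fold seed — internally consistent,
and optimistically biased as a performance estimate for the selected set,
which is why it is a separate step from the scenario evaluation.

## Phantoms

`generate_case` renders: lung-like background at −900 HU; a nodule
(sphere, diameter default 11.91 mm) with optional Gaussian-bump
spiculations, an interior at −30 HU with correlated Gaussian texture
(optionally anisotropic along z), and salt impulses (+150 HU at a
configurable rate); attached vessels as constant-radius (1 mm) tubes along
straight lines or helices starting inside the nodule (helix curvature is
exactly a/(a²+b²)); and optional white HU noise (default σ = 10). Truth
labels (1 = nodule, 2 = vessels, disjoint, vessels attached) and the
centroid seed point accompany each volume. Everything is deterministic
given (spec, seed).

The default cohort emulates the study conditions: 22 cases per class,
diameters ~N(11.91, 4.36) mm truncated below at 4 mm, 512×512-capable
geometry (the test default is 96³ at 0.7 mm isotropic for tractability; a
paper-geometry configuration with 512×512 slices exists and is exercised
once in the tests). Class effects map one generative knob to each `FS_nv`
feature: adenocarcinoma-like cases draw more vessels (Poisson mean 3 vs 2,
minimum 1), tighter helices (winding radius 2–3.5 mm at pitch 1.5 mm,
κ ≈ 0.24–0.32 mm⁻¹, vs 0.2–0.8 mm at pitch 4 mm, κ ≈ 0.01–0.05 mm⁻¹),
more impulses (rate 0.02 vs 0.002), anisotropic texture (z correlation
×2.5), and stronger spiculation (8 × 0.25 vs 2 × 0.1).

What the phantoms do **not** emulate: airways, ribs, pleural contact,
partial-volume and reconstruction-kernel effects, vessel taper and
branching trees, and the intensity overlap of real part-solid nodules with
vessels. Passing tests therefore demonstrate the correctness and
calibration of the estimators and the pipeline plumbing on known geometry
— not clinical discriminative performance. On these phantoms the default
class effects are deliberately large, so cross-validated AUCs near 1.0 for
the vessel-informed feature sets are expected and only the relative
orderings (combined set ≥ subsets; manual ≥ automatic annotation) carry
meaning.

## Numerical choices and problem sizes

Connectivity is 26 everywhere. Quantization upper edges are inclusive.
Zero-variance features return 0 with flags. Curvature tolerance for
"locally straight" is |r′×r″|² < 1e−10. Replicate-level validation suites
(null calibration, power/ordering, segmentation recovery) run cohorts at
64³ voxels @ 0.7 mm — the estimators are resolution-bound, not
extent-bound, and the nodule size distribution fits — while the scenario
grid runs the full default cohort. The null-calibration check uses a
binomial-tolerant assertion (≥ 90% of 20 replicates inside the [0.3, 0.7]
AUC band, mean in [0.4, 0.6]): the band is ±2.1σ of the null CV-AUC at
n = 44, so demanding every replicate stay inside would fail roughly a third
of the time under the very hypothesis being verified.

## Known limitations

* Skeleton-based curvature retains a small positive bias (~5%) from
  residual chain jaggedness; it is stable across cases, so class contrasts
  survive.
* The automatic path loses small nodules (diameter ≲ 5 mm) to the opening
  element — reported as failed cases, never silently dropped.
* A vessel thicker than the opening radius stays fused with the nodule
  (elongation warning).
* Box-counting dimension on short branches (< 16 points or extent < ~4×
  point spacing) is undefined and excluded from the per-case mean.
* The 830-feature texture bank is a documented, versioned composition; its
  family cardinalities are a design choice, and no claim is made that any
  individual feature matches another toolkit's same-named feature
  numerically.
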