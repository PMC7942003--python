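# nodvess

Computer-aided diagnosis (CADx) of indeterminate lung nodules on chest CT:
distinguishing **adenocarcinoma** (the most common malignant histology) from
**granuloma** (its most common benign mimic) using radiomic features of the
nodule *and* the tortuosity of the vessels attached to it. Malignant nodules
recruit vasculature — they pull nearby vessels toward themselves — so the
curvature and count of attached vessels carry diagnostic signal that purely
nodule-centric radiomics misses.

The package is aimed at medical-image-analysis researchers who want a fully
inspectable, ground-truth-testable implementation of this pipeline. Since
clinical CT datasets of biopsy-proven nodules are rarely shareable, a
synthetic phantom generator produces CT-like volumes (nodule + attached
vessels + texture + noise) with exact ground truth for every stage.

## Pipeline

1. **Segmentation** (`nodvess.segmentation`) — from a seed voxel, a
   threshold-based region growing over an HU window (default [−600, 200])
   extracts the nodule plus everything attached; morphological opening with
   a spherical element (default radius 2 mm, built in physical units so
   anisotropic voxels behave) detaches thin tubular structures, yielding a
   nodule mask and labeled attached-vessel components.
2. **Nodule radiomics** (`nodvess.nodule_features`) — 830 texture features
   (first-order, 3D GLCM/Haralick over the 13 unique distance-1 directions
   and their distance-2 counterparts, gradient kernels, multi-scale
   Gaussian/LoG/DoG, wavelet subbands), 13 shape features (sphericity,
   convexity, roughness, ...) from a marching-cubes mesh, and 12 margin
   sharpness features from the HU gradient on the nodule surface.
3. **Vessel tortuosity** (`nodvess.vessel_features`) — skeleton-based
   centerlines per attached vessel, discrete Frenet curvature
   κ = |r′×r″|/|r′|³ and torsion τ = (r′×r″)·r‴/|r′×r″|², the arc/chord
   distance metric, and a box-counting fractal dimension.
4. **Classification** (`nodvess.model`) — linear-kernel SVM (C = 1) on
   z-scored features, stratified threefold cross-validation, AUC via the
   Mann–Whitney rank statistic on pooled decision scores, and greedy forward
   feature selection maximizing that CV AUC.
5. **Scenario grid** (`nodvess.cli_pipeline`) — the 2 × 4 matrix of
   {manual, automatic} annotation × feature set:
   `FS_nv` = {correlation_std, diagonal_gradient_kurtosis, curvature_mean,
   n_attached_vessels}, `FS_n` = the two texture features, `FS_v` = two
   vessel-tortuosity comparison features, `FS_s` = {roughness, convexity,
   sphericity}.

The full per-case vector has 859 features (830 texture + 13 shape +
12 sharpness + 4 vessel) plus two auxiliary vessel comparators used by
`FS_v`; degenerate inputs yield sentinel values with flags, never missing
entries.

## Worked example

```python
from nodvess.phantoms import PhantomSpec, generate_case
from nodvess.cli_pipeline import extract_case

spec = PhantomSpec(nodule_diameter_mm=12, n_vessels=2,
                   helix_radius_mm=2.5, helix_pitch_mm=1.5, helix_turns=2.0)
volume, truth, seed = generate_case(spec, seed=7)
fv = extract_case(volume, seed, "manual", labels=truth)
print("features:", len(fv))
for name in ("correlation_std", "diagonal_gradient_kurtosis",
             "curvature_mean", "n_attached_vessels",
             "sphericity", "roughness"):
    print(f"{name:28s} {fv[name]: .4f}")
```

prints

```
features: 861
correlation_std               0.0595
diagonal_gradient_kurtosis    4.2107
curvature_mean                0.3087
n_attached_vessels            2.0000
sphericity                    1.0141
roughness                     0.0094
```

The helical vessels (winding radius a = 2.5 mm, pitch b = 1.5 mm) have
analytic curvature a/(a² + b²) ≈ 0.294 mm⁻¹; the measured pooled
`curvature_mean` of 0.309 mm⁻¹ reflects the skeleton-based estimate. Both
tubes are recovered (`n_attached_vessels` = 2), the smooth nodule is nearly
spherical (sphericity ≈ 1 up to discretization), and its radial roughness
is near zero.

A command-line interface mirrors the library:

```bash
nodvess phantom --n-per-class 22 --out cohort/       # write a cohort
nodvess segment --volume case.nii.gz --seed case_seed.json --out seg.nii.gz
nodvess features --volume case.nii.gz --seed case_seed.json --out features.csv
nodvess select --features features.csv --labels labels.csv --k 4
nodvess scenarios --n-per-class 22 --out results.json  # the 8-row grid
```

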