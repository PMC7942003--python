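"""Automatic nodule/vessel segmentation from a seed point.

The pipeline is the classical one for juxtavascular nodules: crop a region
of interest around the seed, flood-fill the Hounsfield window that contains
soft tissue (threshold-based region growing), then detach thin tubular
structures from the nodule body by morphological opening with a spherical
element built in physical units. Whatever the opening removes and still
touches the nodule is kept as attached-vessel components.

Connectivity is 26 throughout, both for growing and component labeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateNoduleError, EmptyMaskError, SeedRejectedError
from .volume_io import BinaryMask, SeedPoint, Volume

__all__ = [
    "RGParams",
    "SegmentationResult",
    "extract_roi",
    "region_grow",
    "separate_nodule_vessels",
    "segment_case",
    "ball_element",
]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class RGParams:
    """Region-growing and separation parameters.

    Attributes
    ----------
    hu_low, hu_high : float
        Inclusion window in HU. The default [-600, 200] covers solid,
        part-solid and non-solid nodules as well as contrast-free vessels.
    opening_radius_mm : float
        Radius of the spherical structuring element used to detach vessels.
        Must exceed the vessel radius and stay below the nodule radius.
    roi_half_extent_mm : float
        Half-size of the cubic ROI cropped around the seed.
    min_vessel_mm3 : float
        Residual components smaller than this volume are treated as
        debris of the opening (e.g. shaved spiculations), not vessels.
    """

    hu_low: float = -600.0
    hu_high: float = 200.0
    opening_radius_mm: float = 2.0
    roi_half_extent_mm: float = 25.0
    min_vessel_mm3: float = 2.0

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError("hu_low must be < hu_high")
        if self.opening_radius_mm <= 0 or self.roi_half_extent_mm <= 0:
            raise ValueError("radii must be positive")


@dataclass(frozen=True)
class SegmentationResult:
    """Nodule mask plus labeled attached-vessel components on one grid."""

    nodule: BinaryMask
    vessels: np.ndarray  # integer component IDs >= 1, 0 = background
    n_vessel_components: int

    def __post_init__(self) -> None:
        if self.nodule.shape != self.vessels.shape:
            raise ValueError("nodule and vessel grids differ")
        if np.any(self.nodule.data & (self.vessels > 0)):
            raise ValueError("nodule and vessels overlap")
        n = len(np.unique(self.vessels[self.vessels > 0]))
        if n != self.n_vessel_components:
            raise ValueError("n_vessel_components does not match labels")


def ball_element(radius_mm: float, spacing) -> np.ndarray:
    """Rasterize a sphere of physical radius into an anisotropic voxel grid."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    zz, yy, xx = np.ogrid[
        -half[0]: half[0] + 1, -half[1]: half[1] + 1, -half[2]: half[2] + 1
    ]
    dist2 = (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    return dist2 <= radius_mm**2 + 1e-9


def extract_roi(
    volume: Volume, seed: SeedPoint, params: RGParams
) -> tuple[Volume, SeedPoint]:
    """Crop a cube of half-extent ``roi_half_extent_mm`` around the seed.

    The crop is clamped at image borders; spacing is preserved and the origin
    is shifted so physical coordinates stay consistent. Returns the ROI and
    the seed remapped into ROI voxel coordinates.
    """
    seed.check_bounds(volume.shape)
    spacing = np.asarray(volume.spacing)
    half_vox = np.floor(params.roi_half_extent_mm / spacing).astype(int)
    idx = np.asarray(seed.index)
    lo = np.maximum(idx - half_vox, 0)
    hi = np.minimum(idx + half_vox + 1, np.asarray(volume.shape))
    sub = volume.data[lo[0]: hi[0], lo[1]: hi[1], lo[2]: hi[2]]
    origin = np.asarray(volume.origin) + lo * spacing
    roi = Volume(sub.copy(), volume.spacing, tuple(origin))
    new_seed = SeedPoint(tuple(idx - lo), case_id=seed.case_id, label=seed.label)
    return roi, new_seed


def region_grow(roi: Volume, seed: SeedPoint, params: RGParams) -> BinaryMask:
    """26-connected component of the HU window containing the seed.

    Raises
    ------
    SeedRejectedError
        If the seed voxel intensity lies outside ``[hu_low, hu_high]``.
    """
    seed.check_bounds(roi.shape)
    hu = roi.data[seed.index]
    if not (params.hu_low <= hu <= params.hu_high):
        raise SeedRejectedError(
            f"seed HU {hu:.1f} outside window [{params.hu_low}, {params.hu_high}]"
        )
    window = (roi.data >= params.hu_low) & (roi.data <= params.hu_high)
    labels, _ = ndimage.label(window, structure=_CONN26)
    grown = labels == labels[seed.index]
    return BinaryMask(grown, roi.spacing, roi.origin)


def separate_nodule_vessels(
    grown: BinaryMask, spacing, params: RGParams
) -> SegmentationResult:
    """Split a grown mask into nodule body and attached-vessel components.

    Opening with a sphere of ``opening_radius_mm`` removes structures thinner
    than the element; the largest surviving component, closed back with the
    same element, is the nodule. Residual voxels of the grown mask that form
    26-components adjacent to the nodule are the attached vessels; detached
    fragments are discarded.

    Raises
    ------
    EmptyMaskError
        If the grown mask is empty.
    DegenerateNoduleError
        If opening removes everything (nodule thinner than the element).
    """
    mask = grown.data
    if not mask.any():
        raise EmptyMaskError("grown mask is empty")
    selem = ball_element(params.opening_radius_mm, spacing)
    opened = ndimage.binary_opening(mask, structure=selem)
    if not opened.any():
        raise DegenerateNoduleError(
            f"opening with radius {params.opening_radius_mm} mm removed the whole mask"
        )
    labels, n = ndimage.label(opened, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(opened, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        opened = labels == keep
    # closing restores the bulk eroded by the opening; a one-voxel dilation
    # reclaims the digital boundary shell the round element cannot recover.
    # Clipping to the grown mask keeps nodule ∪ vessels ⊆ grown.
    closed = ndimage.binary_closing(opened, structure=selem)
    nodule = ndimage.binary_dilation(closed, structure=_CONN26) & mask

    _warn_if_elongated(nodule, spacing)

    residual = mask & ~nodule
    vessel_labels = np.zeros(mask.shape, dtype=np.int32)
    n_comp = 0
    if residual.any():
        touch_zone = ndimage.binary_dilation(nodule, structure=_CONN26)
        comp, n_raw = ndimage.label(residual, structure=_CONN26)
        voxel_mm3 = float(np.prod(spacing))
        min_vox = params.min_vessel_mm3 / voxel_mm3
        for lab in range(1, n_raw + 1):
            m = comp == lab
            if m.sum() < min_vox:
                continue
            if np.any(m & touch_zone):
                n_comp += 1
                vessel_labels[m] = n_comp
            else:
                log.debug("discarding detached fragment of %d voxels", int(m.sum()))
    nod_mask = BinaryMask(nodule, grown.spacing, grown.origin)
    return SegmentationResult(nod_mask, vessel_labels, n_comp)


def _warn_if_elongated(nodule: np.ndarray, spacing, ratio: float = 3.0) -> None:
    """Flag nodules whose principal axes are very anisotropic.

    An elongated 'nodule' usually means a vessel thicker than the opening
    element survived and stayed fused with the body.
    """
    pts = np.argwhere(nodule) * np.asarray(spacing)
    if len(pts) < 8:
        return
    cov = np.cov((pts - pts.mean(axis=0)).T)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if ev[1] > 0 and np.sqrt(ev[0] / max(ev[1], 1e-12)) > ratio:
        warnings.warn(
            "nodule is highly elongated; a vessel thicker than the opening "
            "radius may not have been detached",
            stacklevel=2,
        )


def segment_case(
    volume: Volume, seed: SeedPoint, params: RGParams | None = None
) -> tuple[SegmentationResult, Volume, SeedPoint]:
    """ROI crop + region growing + separation in one call.

    Returns the segmentation (on the ROI grid), the ROI volume, and the seed
    in ROI coordinates.
    """
    params = params or RGParams()
    roi, roi_seed = extract_roi(volume, seed, params)
    grown = region_grow(roi, roi_seed, params)
    seg = separate_nodule_vessels(grown, roi.spacing, params)
    return seg, roi, roi_seed
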