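"""Region growing and nodule/vessel separation against constructed truth."""

import numpy as np
import pytest
from scipy import ndimage

from nodvess.errors import DegenerateNoduleError, EmptyMaskError, SeedRejectedError
from nodvess.segmentation import (
    RGParams,
    ball_element,
    extract_roi,
    region_grow,
    segment_case,
    separate_nodule_vessels,
)
from nodvess.volume_io import BinaryMask, SeedPoint, Volume


def _sphere_mask(shape, center, radius_vox):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius_vox**2


def _sphere_tube_volume(tube_radii_vox=(1,), nodule_radius_vox=8):
    """Sphere at center plus axis-aligned tubes of given radii, HU -30/-900."""
    shape = (48, 48, 48)
    c = (24, 24, 24)
    mask = _sphere_mask(shape, c, nodule_radius_vox)
    tubes = np.zeros(shape, dtype=bool)
    axes = [(0, 1), (1, 1), (2, 1), (0, -1), (1, -1), (2, -1)]
    for (axis, sign), r in zip(axes, tube_radii_vox):
        for step in range(nodule_radius_vox, 22):
            pos = list(c)
            pos[axis] += sign * step
            sl = tuple(
                slice(max(p - r, 0), p + r + 1) if a != axis else slice(p, p + 1)
                for a, p in enumerate(pos)
            )
            block = np.zeros(shape, dtype=bool)
            block[sl] = True
            tubes |= block
    vol = np.full(shape, -900.0)
    vol[mask | tubes] = -30.0
    return Volume(vol, (1.0, 1.0, 1.0)), mask, tubes, SeedPoint(c)


def test_roi_extent_arithmetic():
    vol = Volume(np.zeros((64, 64, 64)), (1.0, 1.0, 1.0))
    roi, seed = extract_roi(vol, SeedPoint((32, 32, 32)),
                            RGParams(roi_half_extent_mm=20))
    assert roi.shape == (41, 41, 41)
    assert seed.index == (20, 20, 20)


def test_roi_clamped_at_corner():
    vol = Volume(np.arange(64**3, dtype=float).reshape(64, 64, 64), (1, 1, 1))
    roi, seed = extract_roi(vol, SeedPoint((0, 0, 63)),
                            RGParams(roi_half_extent_mm=20))
    assert roi.shape == (21, 21, 21)
    assert seed.index == (0, 0, 20)
    assert roi.data[seed.index] == vol.data[0, 0, 63]


def test_roi_out_of_bounds_seed_raises():
    vol = Volume(np.zeros((8, 8, 8)), (1, 1, 1))
    with pytest.raises(IndexError):
        extract_roi(vol, SeedPoint((8, 0, 0)), RGParams())


def test_region_grow_recovers_constructed_shapes():
    vol, sphere, tubes, seed = _sphere_tube_volume((1, 1, 1))
    grown = region_grow(vol, seed, RGParams(hu_low=-200, hu_high=200))
    np.testing.assert_array_equal(grown.data, sphere | tubes)


def test_region_grow_seed_in_background_rejected():
    vol, *_ = _sphere_tube_volume()
    with pytest.raises(SeedRejectedError):
        region_grow(vol, SeedPoint((2, 2, 2)), RGParams(hu_low=-200, hu_high=200))


def test_region_grow_connected_and_contains_seed(textured_case):
    vol, labels, seed = textured_case
    params = RGParams()
    roi, rseed = extract_roi(vol, seed, params)
    grown = region_grow(roi, rseed, params)
    assert grown.data[rseed.index]
    _, n = ndimage.label(grown.data, structure=np.ones((3, 3, 3)))
    assert n == 1


@pytest.mark.parametrize("widen", [0.0, 100.0, 300.0])
def test_region_grow_monotone_in_window(textured_case, widen):
    vol, labels, seed = textured_case
    params = RGParams()
    roi, rseed = extract_roi(vol, seed, params)
    narrow = region_grow(roi, rseed, params)
    wide = region_grow(roi, rseed, RGParams(hu_low=params.hu_low - widen,
                                            hu_high=params.hu_high + widen))
    assert np.all(wide.data[narrow.data])


def test_separation_counts_three_tubes_and_recovers_sphere():
    vol, sphere, tubes, seed = _sphere_tube_volume((1, 1, 1), nodule_radius_vox=6)
    params = RGParams(hu_low=-200, hu_high=200, opening_radius_mm=2.0)
    grown = region_grow(vol, seed, params)
    seg = separate_nodule_vessels(grown, vol.spacing, params)
    assert seg.n_vessel_components == 3
    dice = 2 * np.sum(sphere & seg.nodule.data) / (sphere.sum()
                                                   + seg.nodule.sum())
    assert dice >= 0.95
    # invariants: disjoint, subset of grown
    assert not np.any(seg.nodule.data & (seg.vessels > 0))
    assert np.all(grown.data[seg.nodule.data])
    assert np.all(grown.data[seg.vessels > 0])


def test_separation_no_tubes_gives_zero_vessels():
    vol, sphere, _, seed = _sphere_tube_volume(())
    params = RGParams(hu_low=-200, hu_high=200)
    grown = region_grow(vol, seed, params)
    seg = separate_nodule_vessels(grown, vol.spacing, params)
    assert seg.n_vessel_components == 0
    assert not (seg.vessels > 0).any()


def test_fat_tube_not_detached_triggers_elongation_warning():
    # tube radius (3 mm) > opening radius (2 mm): the tube cannot be
    # detached and the fused mask is conspicuously elongated
    shape = (64, 32, 32)
    c = (10, 16, 16)
    mask = _sphere_mask(shape, c, 6)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    tube = (zz >= 10) & (zz < 60) & (((yy - 16) ** 2 + (xx - 16) ** 2) <= 9)
    vol = np.full(shape, -900.0)
    vol[mask | tube] = -30.0
    volume = Volume(vol, (1.0, 1.0, 1.0))
    params = RGParams(hu_low=-200, hu_high=200, opening_radius_mm=2.0)
    grown = region_grow(volume, SeedPoint(c), params)
    with pytest.warns(UserWarning, match="elongated"):
        seg = separate_nodule_vessels(grown, volume.spacing, params)
    assert seg.n_vessel_components == 0  # the fat tube stayed fused


def test_separation_error_paths():
    empty = BinaryMask(np.zeros((8, 8, 8), dtype=bool), (1, 1, 1))
    with pytest.raises(EmptyMaskError):
        separate_nodule_vessels(empty, (1, 1, 1), RGParams())
    thin = np.zeros((16, 16, 16), dtype=bool)
    thin[8, 8, :] = True  # 1-voxel line, thinner than the opening element
    with pytest.raises(DegenerateNoduleError):
        separate_nodule_vessels(BinaryMask(thin, (1, 1, 1)), (1, 1, 1),
                                RGParams(opening_radius_mm=2.0))


def test_ball_element_respects_anisotropic_spacing():
    el = ball_element(2.0, (2.0, 1.0, 1.0))
    assert el.shape == (3, 5, 5)  # 1 voxel reach in z, 2 in y/x
    assert el[1, 2, 2]


def test_roi_contains_truth_nodule_on_phantoms(clean_case):
    vol, labels, seed = clean_case
    params = RGParams()
    roi, rseed = extract_roi(vol, seed, params)
    truth_roi, _ = extract_roi(
        Volume((labels == 1).astype(float), vol.spacing), seed, params)
    assert truth_roi.data.sum() == (labels == 1).sum()


def test_segment_case_end_to_end_matches_truth(clean_case):
    vol, labels, seed = clean_case
    seg, roi, rseed = segment_case(vol, seed)
    truth_roi, _ = extract_roi(
        Volume((labels == 1).astype(float), vol.spacing), seed, RGParams())
    truth = truth_roi.data > 0.5
    dice = 2 * np.sum(truth & seg.nodule.data) / (truth.sum() + seg.nodule.sum())
    assert dice >= 0.95
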