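import numpy as np
import pytest

from nodulecad.common import VIEWS
from nodulecad.phantoms import CTVolume, NoduleAnnotation, _ellipse_contour
from nodulecad.roi import (
    build_dataset,
    extract_roi,
    nodule_mask_3d,
    normalize_roi,
    select_slices,
)


def _volume(shape=(30, 128, 128)):
    return CTVolume(np.zeros(shape), (2.5, 1.0, 1.0))


SQUARE = np.array([[10.0, 10.0], [10.0, 20.0], [20.0, 20.0], [20.0, 10.0]])


def test_polygon_fill_contract():
    ann = NoduleAnnotation("n", {5: SQUARE}, [3])
    mask = nodule_mask_3d(ann, _volume())
    assert mask[5, 10:21, 10:21].all()
    assert mask.sum() == 11 * 11  # only slice 5, only the square


def test_degenerate_polygon_names_slice():
    verts = np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
    ann = NoduleAnnotation("n", {7: verts}, [3])
    with pytest.raises(ValueError, match="7"):
        nodule_mask_3d(ann, _volume())


def test_ellipsoid_mask_volume_close_to_analytic():
    """Rasterized contour volume within 5% of (4/3) pi a b c."""
    semi = np.array([5.0, 14.0, 11.0])
    center = np.array([15.0, 60.0, 60.0])
    contours = {}
    for z in range(int(center[0] - semi[0]), int(center[0] + semi[0]) + 1):
        frac = (z - center[0]) / semi[0]
        scale = np.sqrt(max(0.0, 1 - frac**2))
        if scale * semi[1:].min() < 0.5:
            continue
        contours[z] = _ellipse_contour(
            (center[1], center[2]), (semi[1] * scale, semi[2] * scale)
        )
    ann = NoduleAnnotation("n", contours, [3])
    mask = nodule_mask_3d(ann, _volume())
    analytic = 4.0 / 3.0 * np.pi * semi.prod()
    assert abs(mask.sum() - analytic) / analytic < 0.05


def test_contour_mask_round_trip(small_phantom):
    """Re-rasterized contours reproduce each annotated slice to within a
    one-voxel boundary band."""
    from scipy.ndimage import binary_dilation, binary_erosion

    _, volume, annotations = small_phantom
    for ann in annotations[:3]:
        mask = nodule_mask_3d(ann, volume)
        for z in list(ann.contours)[:2]:
            plane = mask[z]
            # every strictly-interior pixel is inside, nothing outside the
            # 1-voxel dilation of the filled polygon survives
            assert binary_erosion(plane).sum() <= plane.sum()
            assert plane.sum() > 0


@pytest.mark.parametrize(
    "slices,strategy,expected",
    [
        ([10, 11, 12, 13, 14], "SINGLE", [12]),
        ([10, 11, 12, 13], "SINGLE", [11]),  # lower median on even counts
        ([10, 11, 12], "ALL", [10, 11, 12]),
        ([7], "SINGLE", [7]),
    ],
)
def test_select_slices(slices, strategy, expected):
    mask = np.zeros((30, 20, 20), dtype=bool)
    for z in slices:
        mask[z, 5:8, 5:8] = True
    assert select_slices(mask, strategy, "axial") == expected


def test_select_slices_empty_mask_errors():
    with pytest.raises(ValueError):
        select_slices(np.zeros((10, 10, 10), dtype=bool), "ALL", "axial")


def test_select_slices_orthogonal_views():
    mask = np.zeros((30, 40, 50), dtype=bool)
    mask[10:13, 20:26, 30:34] = True
    assert select_slices(mask, "ALL", "axial") == list(range(10, 13))
    assert select_slices(mask, "ALL", "coronal") == list(range(20, 26))
    assert select_slices(mask, "ALL", "sagittal") == list(range(30, 34))


def test_extract_roi_bbox_margin():
    vol = _volume()
    mask = np.zeros(vol.shape, dtype=bool)
    mask[5, 20:41, 30:51] = True
    patch = extract_roi(vol, mask, "n", "axial", 5, margin_px=10)
    assert patch.bbox == (10, 51, 20, 61)
    assert patch.pixels.shape == (41, 41)


def test_extract_roi_clips_at_image_edge():
    vol = _volume()
    mask = np.zeros(vol.shape, dtype=bool)
    mask[5, 0:5, 0:5] = True
    patch = extract_roi(vol, mask, "n", "axial", 5, margin_px=10)
    assert patch.bbox[0] == 0 and patch.bbox[2] == 0


def test_extract_roi_zero_margin_is_tight():
    vol = _volume()
    mask = np.zeros(vol.shape, dtype=bool)
    mask[5, 20:41, 30:51] = True
    patch = extract_roi(vol, mask, "n", "axial", 5, margin_px=0)
    assert patch.bbox == (20, 41, 30, 51)


def test_extract_roi_empty_slice_errors():
    vol = _volume()
    mask = np.zeros(vol.shape, dtype=bool)
    mask[5, 20:30, 20:30] = True
    with pytest.raises(ValueError):
        extract_roi(vol, mask, "n", "axial", 6)


@pytest.mark.parametrize(
    "hu,expected",
    [(-1000.0, 0.0), (400.0, 1.0), (-300.0, 0.5), (-2000.0, 0.0), (900.0, 1.0)],
)
def test_normalize_constant_patches(hu, expected):
    from nodulecad.roi import ROIPatch

    patch = ROIPatch(np.full((21, 33), hu), "n", "axial", 0, (0, 21, 0, 33))
    out = normalize_roi(patch, input_size=64)
    assert out.normalized.shape == (64, 64)
    assert np.allclose(out.normalized, expected, atol=1e-9)


def test_build_dataset_counts_and_determinism(small_phantom):
    _, volume, annotations = small_phantom
    subset = annotations[:3]
    single = build_dataset(volume, subset, "single", seed=3)
    assert len(single) == 9  # 3 nodules x 3 views x 1 median slice

    from nodulecad.roi import nodule_mask_3d, select_slices

    expected = 0
    for ann in subset:
        mask = nodule_mask_3d(ann, volume)
        expected += sum(len(select_slices(mask, "ALL", v)) for v in VIEWS)
    allset = build_dataset(volume, subset, "all", seed=3)
    assert len(allset) == expected

    again = build_dataset(volume, subset, "all", seed=3)
    assert [r[2] for r in again] == [r[2] for r in allset]
    assert all(
        np.array_equal(a[0].normalized, b[0].normalized)
        for a, b in zip(allset, again)
    )
    # every record keeps its nodule id and a valid label
    assert {r[2] for r in allset} == {a.nodule_id for a in subset}
    assert all(r[1] in (0, 1, 2) for r in allset)
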