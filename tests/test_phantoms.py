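import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from nodulecad.common import CLASS_NAMES
from nodulecad.phantoms import (
    GGO_HU,
    PARENCHYMA_HU,
    SOLID_HU,
    SOLID_SD,
    NoduleAnnotation,
    PhantomSpec,
    generate_phantom,
    load_phantom_dataset,
    simulate_annotators,
    write_phantom_dataset,
)
from nodulecad.roi import nodule_mask_3d


def test_generate_shape_and_count():
    spec = PhantomSpec(volume_shape=(40, 128, 128), n_nodules_per_class=1, seed=7)
    volume, annotations = generate_phantom(spec)
    assert volume.shape == (40, 128, 128)
    assert len(annotations) == 3
    assert sorted(a.true_class for a in annotations) == sorted(CLASS_NAMES)
    assert np.all(np.isfinite(volume.voxels))


def test_generate_deterministic_under_seed():
    spec = PhantomSpec(volume_shape=(40, 128, 128), n_nodules_per_class=1, seed=7)
    vol_a, ann_a = generate_phantom(spec)
    vol_b, ann_b = generate_phantom(spec)
    assert np.array_equal(vol_a.voxels, vol_b.voxels)
    for a, b in zip(ann_a, ann_b):
        assert a.scores == b.scores
        assert set(a.contours) == set(b.contours)
        for z in a.contours:
            assert np.array_equal(a.contours[z], b.contours[z])


def test_solid_interior_mean_hu(small_phantom):
    """Sample mean of solid-nodule interiors matches the generator
    distribution within 3 sigma / sqrt(n)."""
    _, volume, annotations = small_phantom
    for ann in annotations:
        if ann.true_class != "solid":
            continue
        # erode in-plane only: thin axial extents would vanish under 3D erosion
        mask = binary_erosion(
            nodule_mask_3d(ann, volume), structure=np.ones((1, 3, 3), dtype=bool)
        )
        values = volume.voxels[mask]
        assert values.size > 30
        tol = 3.0 * SOLID_SD / np.sqrt(values.size) + 5.0  # 5 HU slack for edge voxels
        assert abs(values.mean() - SOLID_HU) < tol


def test_class_attenuation_ordering(small_phantom):
    """Mean interior HU is ordered non-solid < part-solid < solid for
    every generated nodule, the structure the 1-5 score presumes."""
    _, volume, annotations = small_phantom
    means = {name: [] for name in CLASS_NAMES}
    for ann in annotations:
        mask = nodule_mask_3d(ann, volume)
        means[ann.true_class].append(volume.voxels[mask].mean())
    assert max(means["non-solid"]) < min(means["part-solid"])
    assert max(means["part-solid"]) < min(means["solid"])
    # and all nodules are denser than parenchyma
    assert min(min(v) for v in means.values()) > PARENCHYMA_HU + 50


def test_part_solid_is_a_mixture(small_phantom):
    """Part-solid interiors contain both ground-glass and solid voxels."""
    _, volume, annotations = small_phantom
    for ann in annotations:
        if ann.true_class != "part-solid":
            continue
        values = volume.voxels[nodule_mask_3d(ann, volume)]
        assert (values < GGO_HU + 150).mean() > 0.3  # ground-glass shell
        assert (values > SOLID_HU - 150).sum() > 10  # solid core present


@pytest.mark.parametrize(
    "true_score,n_raters,noise_sd,expected",
    [
        (3, 4, 0.0, [3, 3, 3, 3]),
        (1, 3, 0.0, [1, 1, 1]),
    ],
)
def test_simulate_annotators_zero_noise(true_score, n_raters, noise_sd, expected):
    assert simulate_annotators(true_score, n_raters, noise_sd, seed=0) == expected


def test_simulate_annotators_clipping_and_rounding():
    # 3 sigma below 5 is 3.5, so rounded/clipped scores stay in {4, 5}
    scores = simulate_annotators(5, 2, 0.5, seed=1)
    assert all(s in (4, 5) for s in scores)
    # extreme noise still clips into the 1..5 scale
    for seed in range(20):
        (s,) = simulate_annotators(1, 1, 10.0, seed=seed)
        assert 1 <= s <= 5


def test_simulate_annotators_errors():
    with pytest.raises(ValueError):
        simulate_annotators(3, 5, 0.1)
    with pytest.raises(ValueError):
        simulate_annotators(0, 2, 0.1)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"nodule_diameter_range_mm": (2.0, 8.0)},
        {"volume_shape": (20, 128, 128)},
        {"spacing_mm": (0.0, 1.0, 1.0)},
        {"annotators_per_nodule": 5},
        {"n_nodules_per_class": 0},
    ],
)
def test_spec_invariants(kwargs):
    with pytest.raises(ValueError):
        PhantomSpec(**kwargs)


def test_annotation_invariants():
    square = np.array([[10.0, 10.0], [10.0, 20.0], [20.0, 20.0], [20.0, 10.0]])
    with pytest.raises(ValueError):
        NoduleAnnotation("n", {}, [3])  # empty contours
    with pytest.raises(ValueError):
        NoduleAnnotation("n", {5: square[:2]}, [3])  # <3 vertices
    with pytest.raises(ValueError):
        NoduleAnnotation("n", {5: square}, [6])  # score out of range
    with pytest.raises(ValueError):
        NoduleAnnotation("n", {5: square}, [3] * 5)  # too many raters


def test_overlap_failure_is_reported():
    spec = PhantomSpec(
        volume_shape=(32, 40, 40),
        n_nodules_per_class=30,
        nodule_diameter_range_mm=(10.0, 12.0),
        seed=0,
    )
    with pytest.raises((RuntimeError, ValueError)):
        generate_phantom(spec)


def test_dataset_round_trip(tmp_path, small_phantom):
    _, volume, annotations = small_phantom
    manifest = write_phantom_dataset(volume, annotations, tmp_path)
    loaded_vol, loaded_anns = load_phantom_dataset(manifest)
    assert loaded_vol.shape == volume.shape
    assert loaded_vol.spacing_mm == pytest.approx(volume.spacing_mm)
    # volume stored as float32
    assert np.allclose(loaded_vol.voxels, volume.voxels, atol=0.01)
    assert len(loaded_anns) == len(annotations)
    for a, b in zip(annotations, loaded_anns):
        assert a.nodule_id == b.nodule_id
        assert a.scores == b.scores
        assert a.true_class == b.true_class
        for z in a.contours:
            assert np.allclose(a.contours[z], b.contours[z])
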