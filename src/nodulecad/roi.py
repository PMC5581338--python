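"""2D region-of-interest extraction under the SINGLE and ALL slice strategies.

The classifier consumes 2D patches rather than 3D blocks because screening
CT has strongly anisotropic, variable slice thickness; sampling axial,
coronal and sagittal planes ("2.5D multi-view") recovers out-of-plane
information without 3D features.  Two slice-selection strategies are
provided: SINGLE keeps only the median nodule slice of each orthogonal
view; ALL keeps every slice in which the nodule appears, in all three
views.  No resampling to isotropic voxels is performed before slicing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as _fill_polygon
from skimage.transform import resize as _resize

from .common import VIEW_AXES, VIEWS
from .phantoms import CTVolume, NoduleAnnotation

__all__ = [
    "ROIPatch",
    "nodule_mask_3d",
    "select_slices",
    "extract_roi",
    "normalize_roi",
    "build_dataset",
]

#: HU display window used for normalisation; spans aerated lung through
#: soft tissue so ground-glass contrast survives the mapping to [0, 1].
HU_WINDOW = (-1000.0, 400.0)

DEFAULT_MARGIN_PX = 10
DEFAULT_INPUT_SIZE = 64


@dataclass
class ROIPatch:
    """A 2D HU sub-image with provenance.

    ``bbox`` is (row_min, row_max, col_min, col_max), half-open, in the
    coordinates of the view plane.  ``normalized`` holds the fixed-size
    [0, 1] model input once :func:`normalize_roi` has run.
    """

    pixels: np.ndarray
    nodule_id: str
    view: str
    slice_index: int
    bbox: tuple[int, int, int, int]
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.view not in VIEW_AXES:
            raise ValueError(f"unknown view {self.view!r}")
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")


def nodule_mask_3d(annotation: NoduleAnnotation, volume: CTVolume) -> np.ndarray:
    """Rasterize per-slice contours into a 3D boolean mask.

    Polygons are filled on the axial pixel grid (pixel centres, 0-based,
    even-odd rule); coronal and sagittal masks are obtained downstream by
    re-slicing this single array, so the three views always agree.
    """
    shape = volume.shape
    mask = np.zeros(shape, dtype=bool)
    for z, verts in annotation.contours.items():
        if not 0 <= z < shape[0]:
            raise ValueError(f"contour slice {z} outside volume of depth {shape[0]}")
        distinct = np.unique(np.round(verts, 9), axis=0)
        if distinct.shape[0] < 3:
            raise ValueError(
                f"degenerate polygon on slice {z}: fewer than 3 distinct vertices"
            )
        rr, cc = _fill_polygon(verts[:, 0], verts[:, 1], shape=shape[1:])
        mask[z, rr, cc] = True
    if not mask.any():
        raise ValueError("annotation rasterized to an empty mask")
    return mask


def select_slices(mask: np.ndarray, strategy: str, view: str) -> list[int]:
    """Slice indices of ``view`` selected by the given strategy.

    ALL returns every index with a non-empty in-view mask, ascending.
    SINGLE returns the median of that list; for an even count the lower
    median is taken, a deterministic choice unbiased toward either end.
    """
    axis = VIEW_AXES[view]
    other = tuple(a for a in range(3) if a != axis)
    occupied = np.where(mask.any(axis=other))[0]
    if occupied.size == 0:
        raise ValueError(f"mask is empty in view {view!r}")
    strategy = strategy.upper()
    if strategy == "ALL":
        return [int(i) for i in occupied]
    if strategy == "SINGLE":
        return [int(occupied[(occupied.size - 1) // 2])]
    raise ValueError(f"unknown strategy {strategy!r}")


def _view_slice(array3d: np.ndarray, view: str, index: int) -> np.ndarray:
    return np.take(array3d, index, axis=VIEW_AXES[view])


def extract_roi(
    volume: CTVolume,
    mask: np.ndarray,
    nodule_id: str,
    view: str,
    slice_index: int,
    margin_px: int = DEFAULT_MARGIN_PX,
) -> ROIPatch:
    """Cut the nodule bounding box plus a context margin from one slice.

    The box is the tight in-view mask bounding box expanded by
    ``margin_px`` pixels on every side (10 by default, adding anatomic
    context around the lesion) and clipped to the image bounds.
    """
    plane_mask = _view_slice(mask, view, slice_index)
    if not plane_mask.any():
        raise ValueError(
            f"nodule {nodule_id}: empty mask on {view} slice {slice_index}"
        )
    rows, cols = np.where(plane_mask)
    r0 = max(int(rows.min()) - margin_px, 0)
    r1 = min(int(rows.max()) + 1 + margin_px, plane_mask.shape[0])
    c0 = max(int(cols.min()) - margin_px, 0)
    c1 = min(int(cols.max()) + 1 + margin_px, plane_mask.shape[1])
    pixels = np.array(_view_slice(volume.voxels, view, slice_index)[r0:r1, c0:c1])
    return ROIPatch(pixels, nodule_id, view, slice_index, (r0, r1, c0, c1))


def normalize_roi(patch: ROIPatch, input_size: int = DEFAULT_INPUT_SIZE) -> ROIPatch:
    """Window, scale and resample a patch to the square model input.

    HU values are clipped to the window, mapped linearly to [0, 1], and
    resampled to ``input_size`` x ``input_size`` by bilinear interpolation.
    """
    lo, hi = HU_WINDOW
    scaled = (np.clip(patch.pixels.astype(np.float64), lo, hi) - lo) / (hi - lo)
    if scaled.shape != (input_size, input_size):
        scaled = _resize(
            scaled,
            (input_size, input_size),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    patch.normalized = np.clip(scaled, 0.0, 1.0)
    return patch


def extract_nodule_patches(
    volume: CTVolume,
    annotation: NoduleAnnotation,
    strategy: str,
    margin_px: int = DEFAULT_MARGIN_PX,
    input_size: int = DEFAULT_INPUT_SIZE,
    mask: np.ndarray | None = None,
) -> list[ROIPatch]:
    """All normalized patches of one nodule under a slice strategy."""
    if mask is None:
        mask = nodule_mask_3d(annotation, volume)
    patches = []
    for view in VIEWS:
        for idx in select_slices(mask, strategy, view):
            patch = extract_roi(volume, mask, annotation.nodule_id, view, idx, margin_px)
            patches.append(normalize_roi(patch, input_size))
    return patches


def build_dataset(
    volume: CTVolume,
    annotations: list[NoduleAnnotation],
    strategy: str,
    seed: int = 0,
    margin_px: int = DEFAULT_MARGIN_PX,
    input_size: int = DEFAULT_INPUT_SIZE,
) -> list[tuple[ROIPatch, int, str]]:
    """Patch-level records ``(patch, label, nodule_id)``, shuffled.

    The label is the attenuation class mapped from the nodule's mean
    annotator score.  Patches are shuffled irrespective of their parent
    nodule, as done when training the network, but each record retains its
    ``nodule_id`` so cross-validation splits can stay leak-free.
    """
    from .evaluation import map_score_to_class

    records: list[tuple[ROIPatch, int, str]] = []
    for ann in annotations:
        label = map_score_to_class(ann.mean_score)
        for patch in extract_nodule_patches(
            volume, ann, strategy, margin_px=margin_px, input_size=input_size
        ):
            records.append((patch, label, ann.nodule_id))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order]
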