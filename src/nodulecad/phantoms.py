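"""Synthetic CT phantoms with nodules of the three attenuation classes.

Real chest-CT cohorts with multi-radiologist nodule annotations cannot be
redistributed, so the pipeline is exercised end-to-end on generated volumes.
A phantom is a noisy lung-parenchyma background containing non-overlapping
ellipsoidal nodules:

* ``non-solid`` -- ground-glass interior, N(-650, 50^2) HU;
* ``part-solid`` -- ground-glass shell with an eccentric solid core
  (core radius 50% of the nodule radius, centre offset up to 50% of the
  radius) at N(-50, 30^2) HU;
* ``solid`` -- N(-50, 30^2) HU throughout.

Background parenchyma sits at about -870 HU with additive Gaussian noise.
These values are generator design choices from standard lung-CT ranges;
they give the classes the ordinal attenuation structure the 1-5 texture
score presumes, and make no claim of fidelity to any particular scanner.

Each nodule carries per-axial-slice boundary contours and 1-4 simulated
annotator scores produced by a Gaussian round-and-clip rater model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .common import CLASS_NAMES, CLASS_TRUE_SCORE

__all__ = [
    "PhantomSpec",
    "CTVolume",
    "NoduleAnnotation",
    "generate_phantom",
    "simulate_annotators",
    "write_phantom_dataset",
    "load_phantom_dataset",
]

# HU design values (see module docstring).
PARENCHYMA_HU, PARENCHYMA_SD = -870.0, 30.0
GGO_HU, GGO_SD = -650.0, 50.0
SOLID_HU, SOLID_SD = -50.0, 30.0

#: Fraction of the nodule semi-axes occupied by the solid core of a
#: part-solid nodule, and the maximum core-centre offset (fraction of the
#: semi-axes).  The offset makes the solid portion geometrically eccentric,
#: so single median slices can miss it.
CORE_RADIUS_FRACTION = 0.5
CORE_MAX_OFFSET_FRACTION = 0.5

#: Voxels kept clear between a nodule's bounding box and every volume face
#: so a downstream ROI context margin never gets clipped asymmetrically.
PLACEMENT_CLEARANCE_VOX = 12

_CONTOUR_VERTICES = 32
_MIN_CONTOUR_RADIUS_VOX = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic volume.

    Attributes
    ----------
    volume_shape : tuple of int
        Voxels per axis, (z, y, x); every axis must be >= 32.
    spacing_mm : tuple of float
        Voxel size per axis (z, y, x).  The default 1.25 mm slice thickness
        with 1.0 mm in-plane spacing is a thin-slice acquisition (the low
        end of the clinical 1.25-3 mm range); at thicker slices the solid
        core of a part-solid nodule spans only a voxel or two of z and is
        unresolvable in the coronal/sagittal views.
    n_nodules_per_class : int
        Nodules generated for each of the three classes.
    nodule_diameter_range_mm : tuple of float
        Sampled uniformly; the minimum must be >= 4 mm so every nodule
        spans more than one axial slice at default spacing.  The default
        8-14 mm keeps the part-solid core (half the nodule radius) at
        least ~2 mm, i.e. resolvable at the default slice thickness.
    annotators_per_nodule : int or "random"
        Number of simulated raters per nodule (1-4), or ``"random"`` for a
        uniform draw in 1..4 per nodule.  Defaults to 4, the annotation
        depth of multi-reader thoracic CT studies.
    rater_noise_sd : float
        Standard deviation, in score units, of the Gaussian rater noise.
    seed : int
        Seed for all randomness in the generator.
    """

    volume_shape: tuple[int, int, int] = (64, 160, 160)
    spacing_mm: tuple[float, float, float] = (1.25, 1.0, 1.0)
    n_nodules_per_class: int = 30
    nodule_diameter_range_mm: tuple[float, float] = (8.0, 14.0)
    annotators_per_nodule: int | str = 4
    rater_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or any(s < 32 for s in self.volume_shape):
            raise ValueError("volume_shape must be three axes, each >= 32")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        lo, hi = self.nodule_diameter_range_mm
        if lo < 4.0:
            raise ValueError(
                "nodule diameter minimum must be >= 4 mm so nodules span "
                "more than one slice"
            )
        if hi < lo:
            raise ValueError("nodule_diameter_range_mm must be (min, max)")
        if self.n_nodules_per_class < 1:
            raise ValueError("n_nodules_per_class must be >= 1")
        if self.annotators_per_nodule != "random" and not (
            1 <= int(self.annotators_per_nodule) <= 4
        ):
            raise ValueError("annotators_per_nodule must be 1..4 or 'random'")
        if self.rater_noise_sd < 0:
            raise ValueError("rater_noise_sd must be >= 0")


@dataclass
class CTVolume:
    """A 3D HU-valued volume with per-axis voxel spacing.

    Axis order is fixed as (z, y, x); axial slices are indexed by z.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass
class NoduleAnnotation:
    """Per-slice contours plus 1-4 annotator texture scores for one nodule.

    ``contours`` maps an axial slice index to an (n, 2) array of (row, col)
    polygon vertices in 0-based pixel coordinates.  ``true_class`` is a
    generator-only label unavailable for real data.
    """

    nodule_id: str
    contours: dict[int, np.ndarray]
    scores: list[int]
    true_class: str | None = None

    def __post_init__(self) -> None:
        if not self.contours:
            raise ValueError("contours must be non-empty")
        self.contours = {
            int(z): np.asarray(v, dtype=float) for z, v in self.contours.items()
        }
        for z, verts in self.contours.items():
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError(f"contour on slice {z} needs >= 3 (row, col) vertices")
        if not 1 <= len(self.scores) <= 4:
            raise ValueError("scores must hold 1..4 annotator ratings")
        if any(int(s) != s or not 1 <= s <= 5 for s in self.scores):
            raise ValueError("every score must be an integer in 1..5")
        self.scores = [int(s) for s in self.scores]
        if self.true_class is not None and self.true_class not in CLASS_NAMES:
            raise ValueError(f"unknown true_class {self.true_class!r}")

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))

    @property
    def true_score(self) -> int | None:
        if self.true_class is None:
            return None
        return CLASS_TRUE_SCORE[self.true_class]


def simulate_annotators(
    true_score: int,
    n_raters: int,
    noise_sd: float,
    seed: int | np.random.Generator | None = None,
) -> list[int]:
    """Simulate integer 1-5 ratings from ``n_raters`` noisy annotators.

    Each rater reports ``round(true_score + N(0, noise_sd^2))`` clipped to
    [1, 5], the simplest model that reproduces the adjacent-category
    disagreements seen between human raters.
    """
    if not 1 <= true_score <= 5:
        raise ValueError("true_score must be in 1..5")
    if not 1 <= n_raters <= 4:
        raise ValueError("n_raters must be in 1..4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = true_score + rng.normal(0.0, noise_sd, size=n_raters)
    return [int(s) for s in np.clip(np.rint(raw), 1, 5)]


def _ellipse_contour(
    center_rc: tuple[float, float], radii_rc: tuple[float, float]
) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, _CONTOUR_VERTICES, endpoint=False)
    rows = center_rc[0] + radii_rc[0] * np.cos(t)
    cols = center_rc[1] + radii_rc[1] * np.sin(t)
    return np.column_stack([rows, cols])


def _ellipsoid_mask(
    shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray
) -> np.ndarray:
    """Boolean voxel-centre mask of an axis-aligned ellipsoid."""
    lo = np.maximum(np.floor(center - semi).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi).astype(int) + 1, shape)
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    inside = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, list[NoduleAnnotation]]:
    """Generate one phantom volume and its nodule annotations.

    Nodules are placed by rejection sampling; a nodule that would overlap
    another or exit the volume is repositioned up to 100 times before the
    generator fails.  Fully reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    voxels = rng.normal(PARENCHYMA_HU, PARENCHYMA_SD, size=shape)

    placed: list[tuple[np.ndarray, float]] = []  # (centre in mm, bounding radius mm)
    annotations: list[NoduleAnnotation] = []
    idx = 0
    for cname in CLASS_NAMES:
        for _ in range(spec.n_nodules_per_class):
            for _attempt in range(100):
                diameter = rng.uniform(*spec.nodule_diameter_range_mm)
                semi_mm = 0.5 * diameter * rng.uniform(0.8, 1.2, size=3)
                semi_vox = semi_mm / spacing
                margin = semi_vox + PLACEMENT_CLEARANCE_VOX
                if np.any(margin * 2 >= np.asarray(shape)):
                    raise ValueError("volume too small for requested nodule size")
                center_vox = np.array(
                    [rng.uniform(m, s - m) for m, s in zip(margin, shape)]
                )
                center_mm = center_vox * spacing
                r_mm = float(semi_mm.max())
                if all(
                    np.linalg.norm(center_mm - c) > r_mm + r + 3.0
                    for c, r in placed
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place nodule {idx} without overlap after 100 tries; "
                    "reduce n_nodules_per_class or enlarge the volume"
                )
            placed.append((center_mm, r_mm))

            mask = _ellipsoid_mask(shape, center_vox, semi_vox)
            n_inside = int(mask.sum())
            if cname == "non-solid":
                voxels[mask] = rng.normal(GGO_HU, GGO_SD, size=n_inside)
            elif cname == "solid":
                voxels[mask] = rng.normal(SOLID_HU, SOLID_SD, size=n_inside)
            else:  # part-solid: ground-glass shell with an eccentric solid core
                voxels[mask] = rng.normal(GGO_HU, GGO_SD, size=n_inside)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                offset = (
                    direction
                    * rng.uniform(0.0, CORE_MAX_OFFSET_FRACTION)
                    * semi_vox
                )
                core = _ellipsoid_mask(
                    shape, center_vox + offset, CORE_RADIUS_FRACTION * semi_vox
                )
                voxels[core] = rng.normal(SOLID_HU, SOLID_SD, size=int(core.sum()))

            contours: dict[int, np.ndarray] = {}
            z0, z1 = center_vox[0] - semi_vox[0], center_vox[0] + semi_vox[0]
            for z in range(int(np.ceil(z0)), int(np.floor(z1)) + 1):
                frac = (z - center_vox[0]) / semi_vox[0]
                scale = np.sqrt(max(0.0, 1.0 - frac * frac))
                radii = (semi_vox[1] * scale, semi_vox[2] * scale)
                if min(radii) < _MIN_CONTOUR_RADIUS_VOX:
                    continue  # skip tip caps too small to enclose a pixel
                contours[z] = _ellipse_contour(
                    (center_vox[1], center_vox[2]), radii
                )

            true_score = CLASS_TRUE_SCORE[cname]
            if spec.annotators_per_nodule == "random":
                n_raters = int(rng.integers(1, 5))
            else:
                n_raters = int(spec.annotators_per_nodule)
            scores = simulate_annotators(true_score, n_raters, spec.rater_noise_sd, rng)
            annotations.append(
                NoduleAnnotation(
                    nodule_id=f"nodule-{idx:03d}",
                    contours=contours,
                    scores=scores,
                    true_class=cname,
                )
            )
            idx += 1

    return CTVolume(voxels, tuple(spec.spacing_mm)), annotations


# ---------------------------------------------------------------------------
# On-disk dataset: NIfTI volume + one JSON per nodule + a manifest CSV.

def _annotation_to_json(ann: NoduleAnnotation) -> dict:
    return {
        "nodule_id": ann.nodule_id,
        "contours": {str(z): v.tolist() for z, v in sorted(ann.contours.items())},
        "scores": ann.scores,
        "true_class": ann.true_class,
    }


def _annotation_from_json(obj: dict) -> NoduleAnnotation:
    return NoduleAnnotation(
        nodule_id=obj["nodule_id"],
        contours={int(z): np.asarray(v) for z, v in obj["contours"].items()},
        scores=list(obj["scores"]),
        true_class=obj.get("true_class"),
    )


def write_phantom_dataset(
    volume: CTVolume,
    annotations: list[NoduleAnnotation],
    outdir: str | Path,
    stem: str = "phantom",
) -> Path:
    """Write a phantom to ``outdir`` and return the manifest path."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # NIfTI affine carries (x, y, z) spacing; voxel array is (z, y, x).
    affine = np.diag(
        [volume.spacing_mm[2], volume.spacing_mm[1], volume.spacing_mm[0], 1.0]
    )
    vol_path = outdir / f"{stem}.nii.gz"
    nib.save(
        nib.Nifti1Image(
            np.asarray(volume.voxels, dtype=np.float32).transpose(2, 1, 0), affine
        ),
        vol_path,
    )
    rows = []
    for ann in annotations:
        ann_path = outdir / f"{stem}_{ann.nodule_id}.json"
        ann_path.write_text(
            json.dumps(_annotation_to_json(ann), sort_keys=True, indent=None)
        )
        rows.append(
            {
                "volume": vol_path.name,
                "annotation": ann_path.name,
                "nodule_id": ann.nodule_id,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_phantom_dataset(
    manifest_path: str | Path,
) -> tuple[CTVolume, list[NoduleAnnotation]]:
    """Load the volume and annotations listed in a manifest CSV."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    if table.empty:
        raise ValueError(f"manifest {manifest_path} lists no nodules")
    vol_names = table["volume"].unique()
    if len(vol_names) != 1:
        raise ValueError("expected a single-volume dataset")
    img = nib.load(base / vol_names[0])
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    voxels = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    volume = CTVolume(voxels, (float(zooms[2]), float(zooms[1]), float(zooms[0])))
    annotations = [
        _annotation_from_json(json.loads((base / name).read_text()))
        for name in table["annotation"]
    ]
    return volume, annotations
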