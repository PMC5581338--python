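"""Contourlet decomposition used as training-time data augmentation.

The contourlet transform combines a Laplacian pyramid (multiscale) with a
directional filter bank (multidirection): each pyramid detail band is split
into angular components, so edges and oriented texture land in different
sub-bands.  Feeding the sub-band images to the classifier alongside the
original ROI diversifies the training set without new annotations.

Implementation notes: the pyramid stores residual details
(``detail = x - upsample(downsample(x))``), making reconstruction exact by
construction; the directional filter bank is realised in the frequency
domain by partitioning the DFT plane into angular wedge pairs (a wedge and
its point reflection), so every component is real and the components sum
back to the band exactly.  This spectral-partition design trades critical
sampling, which the augmentation role does not need, for exact perfect
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "ContourletBands",
    "lp_decompose",
    "lp_reconstruct",
    "dfb_decompose",
    "contourlet_decompose",
    "contourlet_reconstruct",
    "augment_roi",
    "ContourletAugmenter",
]

#: 5-tap Gaussian pyramid kernel with DC gain exactly 1.
_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

DEFAULT_LEVELS = 2
DEFAULT_DIRECTIONS = (4, 4)


@dataclass
class ContourletBands:
    """Lowpass band plus per-level directional components of one image.

    ``directional[level][i]`` is the i-th angular component of the pyramid
    detail band at ``level`` (level 0 is the finest scale, at full input
    resolution).
    """

    lowpass: np.ndarray
    directional: list[list[np.ndarray]]
    levels: int
    directions_per_level: tuple[int, ...]


def _blur(image: np.ndarray) -> np.ndarray:
    out = convolve1d(image, _KERNEL, axis=0, mode="reflect")
    return convolve1d(out, _KERNEL, axis=1, mode="reflect")


def _down(image: np.ndarray) -> np.ndarray:
    return _blur(image)[::2, ::2]


def _up_axis(image: np.ndarray, axis: int) -> np.ndarray:
    shape = list(image.shape)
    shape[axis] *= 2
    stuffed = np.zeros(shape, dtype=image.dtype)
    taken = [slice(None)] * image.ndim
    taken[axis] = slice(None, None, 2)
    stuffed[tuple(taken)] = image
    mask = np.zeros(shape, dtype=image.dtype)
    mask[tuple(taken)] = 1.0
    # Normalized interpolation: dividing by the convolved sample mask keeps
    # unit DC gain everywhere, including at the reflected borders.
    num = convolve1d(stuffed, 2.0 * _KERNEL, axis=axis, mode="reflect")
    den = convolve1d(mask, 2.0 * _KERNEL, axis=axis, mode="reflect")
    return num / den


def _up(image: np.ndarray) -> np.ndarray:
    return _up_axis(_up_axis(image, 0), 1)


def _check_square(image: np.ndarray, levels: int) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    if image.shape[0] % (1 << levels):
        raise ValueError(
            f"side {image.shape[0]} not divisible by 2^{levels}"
        )
    return image


def lp_decompose(image: np.ndarray, levels: int) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Laplacian pyramid: per-level approximations and residual details.

    Returns ``(approximations, details)`` where ``approximations[k]`` has
    side ``n / 2^(k+1)`` and ``details[k]`` is the residual at side
    ``n / 2^k``.  Because details store exact residuals, reconstruction is
    lossless regardless of the blur kernel.
    """
    image = _check_square(image, levels)
    approximations, details = [], []
    current = image
    for _ in range(levels):
        coarse = _down(current)
        details.append(current - _up(coarse))
        approximations.append(coarse)
        current = coarse
    return approximations, details


def lp_reconstruct(lowpass: np.ndarray, details: list[np.ndarray]) -> np.ndarray:
    """Invert :func:`lp_decompose` exactly."""
    current = np.asarray(lowpass, dtype=np.float64)
    for detail in reversed(details):
        current = _up(current) + detail
    return current


def _wedge_index(shape: tuple[int, int], n_directions: int) -> np.ndarray:
    """Assign every DFT bin to one of ``n_directions`` angular wedges.

    Wedges are centred on angles k*pi/n (k = 0..n-1) so an axis-aligned
    sinusoid falls in the middle of a wedge, and each wedge includes its
    point reflection (angles are taken modulo pi), keeping components real.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    theta = np.mod(np.arctan2(fy, fx), np.pi)
    half = np.pi / (2 * n_directions)
    wedge = np.floor(np.mod(theta + half, np.pi) / (np.pi / n_directions)).astype(int)
    # Nyquist bins alias +-0.5 and would land in different wedges than their
    # point reflections; symmetrize so every component stays real.
    refl = wedge[(-np.arange(shape[0])) % shape[0]][:, (-np.arange(shape[1])) % shape[1]]
    return np.minimum(wedge, refl)


def dfb_decompose(band: np.ndarray, n_directions: int) -> list[np.ndarray]:
    """Split a band into real directional components that sum to the band.

    The DFT plane is partitioned into ``n_directions`` wedge pairs;
    component i is the inverse DFT of the spectrum masked to wedge i.
    Since the masks partition the plane, the components sum to the input
    exactly, and disjoint spectral supports give Parseval-additive
    energies.
    """
    if n_directions < 2 or n_directions & (n_directions - 1):
        raise ValueError("n_directions must be a power of two >= 2")
    band = np.asarray(band, dtype=np.float64)
    spectrum = np.fft.fft2(band)
    wedge = _wedge_index(band.shape, n_directions)
    components = []
    for i in range(n_directions):
        masked = np.where(wedge == i, spectrum, 0.0)
        components.append(np.real(np.fft.ifft2(masked)))
    return components


def contourlet_decompose(
    image: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    directions: tuple[int, ...] = DEFAULT_DIRECTIONS,
) -> ContourletBands:
    """Full decomposition: Laplacian pyramid, then a DFB per detail level."""
    if len(directions) != levels:
        raise ValueError("need one direction count per pyramid level")
    approximations, details = lp_decompose(image, levels)
    directional = [
        dfb_decompose(detail, n_dir) for detail, n_dir in zip(details, directions)
    ]
    return ContourletBands(
        lowpass=approximations[-1],
        directional=directional,
        levels=levels,
        directions_per_level=tuple(directions),
    )


def contourlet_reconstruct(bands: ContourletBands) -> np.ndarray:
    """Invert :func:`contourlet_decompose`; exact to float64 round-off."""
    details = [sum(components) for components in bands.directional]
    return lp_reconstruct(bands.lowpass, details)


def _band_to_image(bands: ContourletBands, lowpass: bool, level: int | None) -> np.ndarray:
    """Reconstruct a single band alone back to image space."""
    zero_low = np.zeros_like(bands.lowpass)
    details = [np.zeros_like(sum(c)) for c in bands.directional]
    if lowpass:
        return lp_reconstruct(bands.lowpass, details)
    details[level] = sum(bands.directional[level])
    return lp_reconstruct(zero_low, details)


def _rescale_unit(image: np.ndarray) -> np.ndarray:
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-12:  # flat band (e.g. zero input): leave as zeros
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def augment_roi(
    normalized_patch: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    directions: tuple[int, ...] = DEFAULT_DIRECTIONS,
    enabled: bool = True,
) -> list[np.ndarray]:
    """Training images derived from one normalized patch.

    Returns the original patch, the lowpass-only image, and one
    directional-sum image per pyramid level, each min-max rescaled to
    [0, 1].  With the default 2 levels that is 4 training images per
    patch.  Augmented bands are used at training time only; test patches
    are always the originals.
    """
    patch = np.asarray(normalized_patch, dtype=np.float64)
    if not enabled:
        return [patch]
    bands = contourlet_decompose(patch, levels, directions)
    # The lowpass image is a unit-DC-gain average of [0, 1] data, so it is
    # clipped rather than min-max stretched: stretching would erase the
    # absolute-attenuation cue that separates ground-glass from solid.
    # Zero-mean directional residuals carry no absolute level, so they are
    # min-max rescaled (flat bands stay zero).
    images = [patch, np.clip(_band_to_image(bands, True, None), 0.0, 1.0)]
    for level in range(levels):
        images.append(_rescale_unit(_band_to_image(bands, False, level)))
    return images


class ContourletAugmenter:
    """Thin scikit-learn-style wrapper expanding (X, y) with band images."""

    def __init__(
        self,
        levels: int = DEFAULT_LEVELS,
        directions: tuple[int, ...] = DEFAULT_DIRECTIONS,
        enabled: bool = True,
    ):
        self.levels = levels
        self.directions = directions
        self.enabled = enabled

    def get_params(self, deep: bool = True) -> dict:
        return {
            "levels": self.levels,
            "directions": self.directions,
            "enabled": self.enabled,
        }

    def set_params(self, **params) -> "ContourletAugmenter":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "ContourletAugmenter":
        return self

    def augment(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Expand a stack of patches (n, h, w) and labels in lock-step."""
        out_x, out_y = [], []
        for patch, label in zip(X, y):
            for image in augment_roi(patch, self.levels, self.directions, self.enabled):
                out_x.append(image)
                out_y.append(label)
        return np.asarray(out_x), np.asarray(out_y)
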