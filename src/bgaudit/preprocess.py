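"""Image augmentation and leukocyte obfuscation.

The audited pipeline applies at most one augmentation (Gaussian blur,
median blur, or multiplicative Gaussian noise), then covers every
annotated leukocyte with a black rectangle.  Augmentation always precedes
obfuscation so the black fill is exact, and the returned boolean mask
marks obfuscated pixels for exclusion from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import footprint_rectangle

from .image import AnnotatedImage

#: kernel → Gaussian σ rule used by mainstream image libraries when only a
#: kernel size is given.
def kernel_sigma(kernel: int) -> float:
    return 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8


@dataclass(frozen=True)
class AugmentationSpec:
    """One augmentation step: kind plus the single parameter it needs.

    ``kind`` is one of ``none``, ``gaussian_blur``, ``median_blur``,
    ``gaussian_noise``.  Blurs take an odd ``kernel`` ≥ 3; noise takes the
    Gaussian ``sigma`` of the multiplicative model x' = ⌊x·(1+n)⌋,
    n ~ N(0, σ).
    """

    kind: str = "none"
    kernel: int | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian_blur", "median_blur", "gaussian_noise"):
            raise ValueError(f"unknown augmentation kind {self.kind!r}")
        if self.kind in ("gaussian_blur", "median_blur"):
            _check_kernel(self.kernel)
            if self.sigma is not None:
                raise ValueError("sigma is only valid for gaussian_noise")
        elif self.kind == "gaussian_noise":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian_noise requires sigma > 0")
            if self.kernel is not None:
                raise ValueError("kernel is only valid for blur kinds")
        elif self.kernel is not None or self.sigma is not None:
            raise ValueError("kind 'none' takes no parameters")

    @property
    def blur_sigma(self) -> float:
        """Gaussian σ derived from the kernel size (blur kinds only)."""
        if self.kind != "gaussian_blur":
            raise ValueError("blur_sigma only defined for gaussian_blur")
        return kernel_sigma(self.kernel)

    def describe(self) -> str:
        if self.kind == "none":
            return "none"
        if self.kind == "gaussian_noise":
            return f"gaussian_noise(sigma={self.sigma})"
        return f"{self.kind}(kernel={self.kernel})"


def _check_kernel(kernel) -> None:
    if kernel is None or kernel < 3 or kernel % 2 == 0:
        raise ValueError(f"kernel must be an odd integer >= 3, got {kernel}")


@dataclass
class ObfuscationMask:
    """Boolean raster; True marks pixels excluded from all statistics."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def empty(cls, height: int, width: int) -> "ObfuscationMask":
        return cls(np.zeros((height, width), dtype=bool))


def gaussian_blur(image: AnnotatedImage, kernel: int) -> AnnotatedImage:
    """Blur each channel with a normalized truncated 2-D Gaussian kernel.

    σ follows the standard kernel-size rule (:func:`kernel_sigma`); the
    support is exactly ``kernel × kernel`` and borders reflect.
    """
    _check_kernel(kernel)
    sigma = kernel_sigma(kernel)
    radius = (kernel - 1) // 2
    out = np.empty_like(image.pixels, dtype=np.float64)
    for c in range(3):
        out[..., c] = ndimage.gaussian_filter(
            image.pixels[..., c].astype(np.float64),
            sigma=sigma,
            radius=radius,
            mode="reflect",
        )
    return _with_pixels(image, np.clip(np.round(out), 0, 255).astype(np.uint8))


def median_blur(image: AnnotatedImage, kernel: int) -> AnnotatedImage:
    """Replace each pixel by the median of its kernel×kernel window.

    Uses the 8-bit histogram-based rank filter (O(k) per pixel, which
    matters at kernel 51) on an explicitly edge-mirrored raster, so border
    semantics match the Gaussian blur's reflective padding.
    """
    _check_kernel(kernel)
    r = (kernel - 1) // 2
    footprint = footprint_rectangle((kernel, kernel))
    out = np.empty_like(image.pixels)
    for c in range(3):
        padded = np.pad(image.pixels[..., c], r, mode="symmetric")
        out[..., c] = rank.median(padded, footprint)[r:-r, r:-r]
    return _with_pixels(image, out)


def gaussian_noise(
    image: AnnotatedImage, sigma: float, rng: np.random.Generator
) -> AnnotatedImage:
    """Multiplicative Gaussian noise: x' = ⌊x·(1+n)⌋, n ~ N(0, σ).

    Noise is drawn independently per pixel per channel; the result is
    clamped to [0, 255].  Black pixels stay black.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    n = rng.normal(0.0, sigma, size=image.pixels.shape)
    out = np.floor(image.pixels.astype(np.float64) * (1.0 + n))
    return _with_pixels(image, np.clip(out, 0, 255).astype(np.uint8))


def obfuscate(image: AnnotatedImage) -> tuple[AnnotatedImage, ObfuscationMask]:
    """Black out every annotated box; the mask is True exactly there.

    Idempotent; an image with no boxes comes back unchanged with an
    all-False mask.
    """
    h, w = image.shape
    mask = np.zeros((h, w), dtype=bool)
    for x0, y0, x1, y1 in image.boxes:
        mask[y0:y1, x0:x1] = True
    pixels = image.pixels.copy()
    pixels[mask] = 0
    return _with_pixels(image, pixels), ObfuscationMask(mask)


def apply_augmentation(
    image: AnnotatedImage,
    aug: AugmentationSpec,
    rng: np.random.Generator | None = None,
) -> AnnotatedImage:
    """Apply one augmentation step; ``none`` returns a copy."""
    if aug.kind == "none":
        return image.copy()
    if aug.kind == "gaussian_blur":
        return gaussian_blur(image, aug.kernel)
    if aug.kind == "median_blur":
        return median_blur(image, aug.kernel)
    if rng is None:
        raise ValueError("gaussian_noise requires an rng")
    return gaussian_noise(image, aug.sigma, rng)


def preprocess_pipeline(
    image: AnnotatedImage,
    aug: AugmentationSpec,
    obfuscate_flag: bool,
    rng: np.random.Generator | None = None,
) -> tuple[AnnotatedImage, ObfuscationMask]:
    """Augment first, then (optionally) obfuscate.

    Returns the processed image and the exclusion mask; when
    ``obfuscate_flag`` is False the mask is all-False.
    """
    augmented = apply_augmentation(image, aug, rng)
    if obfuscate_flag:
        return obfuscate(augmented)
    return augmented, ObfuscationMask.empty(*image.shape)


def _with_pixels(image: AnnotatedImage, pixels: np.ndarray) -> AnnotatedImage:
    return AnnotatedImage(
        pixels=pixels, boxes=list(image.boxes), label=image.label, id=image.id
    )
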