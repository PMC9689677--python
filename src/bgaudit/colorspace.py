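"""Color-channel selection, RGB→HSV conversion, and circular hue arithmetic.

Hue lives on a circle: red at 0°, yellow 60°, green 120°, aqua 180°,
blue 240°, purple 300°.  Internally hue is stored on the *half-degree*
scale ``[0, 180)`` (1 unit = 2°), the encoding common to 8-bit image
libraries; the degree-scale API :func:`hue_distance` converts at the
boundary.  Saturation and value are rescaled to ``[0, 255]``.

Two hue formulations are provided: the hexcone (max/min sector) formula,
which is the primary path, and an arccos-based formulation
(:func:`rgb_to_hue_arccos`) that computes the same angle from the chromatic
plane projection.  For saturated pixels they agree to floating-point
precision; both map achromatic pixels (R = G = B) to hue 0 by convention.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

#: Full-scale histogram range per channel (upper edge exclusive).
CHANNEL_RANGES: dict[str, tuple[float, float]] = {
    "R": (0.0, 256.0),
    "G": (0.0, 256.0),
    "B": (0.0, 256.0),
    "H": (0.0, 180.0),
    "S": (0.0, 256.0),
    "V": (0.0, 256.0),
}


class Channel(str, Enum):
    """One color channel of the RGB or HSV encoding."""

    R = "R"
    G = "G"
    B = "B"
    H = "H"
    S = "S"
    V = "V"

    @property
    def range(self) -> tuple[float, float]:
        return CHANNEL_RANGES[self.value]

    @property
    def needs_hsv(self) -> bool:
        return self.value in ("H", "S", "V")


def rgb_to_hsv(pixels: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to HSV.

    Parameters
    ----------
    pixels
        ``(..., 3)`` array of RGB intensities in ``[0, 255]``.

    Returns
    -------
    ndarray
        Float array of the same shape with H on the half-degree scale
        ``[0, 180)`` and S, V in ``[0, 255]``.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim < 1 or pixels.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) RGB input, got {pixels.shape}")
    rgb = pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    big = np.max(rgb, axis=-1)
    small = np.min(rgb, axis=-1)
    chroma = big - small

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(big > 0, (1.0 - small / np.where(big > 0, big, 1.0)), 0.0)
        safe_c = np.where(chroma > 0, chroma, 1.0)
        hue_deg = np.select(
            [chroma == 0, big == r, big == g],
            [
                np.zeros_like(big),
                (60.0 * ((g - b) / safe_c)) % 360.0,
                60.0 * ((b - r) / safe_c) + 120.0,
            ],
            default=60.0 * ((r - g) / safe_c) + 240.0,
        )

    out = np.empty_like(rgb)
    out[..., 0] = hue_deg / 2.0          # half-degree scale, [0, 180)
    out[..., 1] = sat * 255.0
    out[..., 2] = big                    # V = max/255, rescaled to [0, 255]
    return out


def rgb_to_hue_arccos(pixels: np.ndarray) -> np.ndarray:
    """Hue via the arccos chromatic-plane formula, on the half-degree scale.

    ``H = arccos((R − G/2 − B/2) / sqrt(R² + G² + B² − RB − RG − GB))``
    for ``G ≥ B``, and ``360° − arccos(...)`` for ``B > G``.  Achromatic
    pixels, where the radicand vanishes, map to hue 0.
    """
    pixels = np.asarray(pixels)
    if pixels.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) RGB input, got {pixels.shape}")
    rgb = pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    num = r - 0.5 * g - 0.5 * b
    rad = r * r + g * g + b * b - r * b - r * g - g * b
    gray = rad <= 0
    denom = np.sqrt(np.where(gray, 1.0, rad))
    cosang = np.clip(num / denom, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    hue_deg = np.where(b > g, 360.0 - ang, ang) % 360.0
    hue_deg = np.where(gray, 0.0, hue_deg)
    return hue_deg / 2.0


def hue_distance(a, b):
    """Shortest arc between two hue coordinates, in degrees.

    Both inputs are in degrees on ``[0, 360)``; the result is
    ``min(|a − b|, 360 − |a − b|)`` and lies in ``[0, 180]``.  Red (0°) and
    purple (300°) are 60° apart, not 300°.
    """
    a_arr = np.asarray(a, dtype=np.float64)
    b_arr = np.asarray(b, dtype=np.float64)
    if np.any(a_arr < 0) or np.any(a_arr >= 360) or np.any(b_arr < 0) or np.any(b_arr >= 360):
        raise ValueError("hue coordinates must lie in [0, 360)")
    diff = np.abs(a_arr - b_arr)
    out = np.minimum(diff, 360.0 - diff)
    return float(out) if np.isscalar(a) and np.isscalar(b) else out


def select_channel(pixels: np.ndarray, channel: Channel | str) -> np.ndarray:
    """Extract one channel plane, converting to HSV when needed.

    Returns a float ``(H, W)`` plane: R/G/B read straight from the raster,
    H on the half-degree scale, S/V on ``[0, 255]``.
    """
    channel = Channel(channel)
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) raster, got {pixels.shape}")
    if channel.needs_hsv:
        hsv = rgb_to_hsv(pixels)
        return hsv[..., "HSV".index(channel.value)]
    return pixels[..., "RGB".index(channel.value)].astype(np.float64)
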