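"""Reduce a channel plane to a 30-bin density vector.

The value distribution of one channel — computed over unmasked pixels
only — is the feature representation for every classifier in the
pipeline.  Bins are equal-width over the channel's full range
([0, 180) for hue on the half-degree scale, [0, 256) otherwise), so two
images are always binned on the same grid regardless of their content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import Channel, select_channel
from .preprocess import ObfuscationMask

DEFAULT_N_BINS = 30


class EmptyHistogramError(ValueError):
    """Raised when every pixel of a plane is masked out."""


@dataclass
class DensityVector:
    """Normalized equal-width histogram of one channel's pixel values."""

    density: np.ndarray
    channel: Channel
    n_pixels_used: int

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.density.ndim != 1:
            raise ValueError("density must be 1-D")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        if abs(self.density.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"densities must sum to 1, got {self.density.sum():.12f}"
            )

    @property
    def n_bins(self) -> int:
        return self.density.shape[0]


def channel_histogram(
    plane: np.ndarray,
    mask: ObfuscationMask | np.ndarray | None,
    channel: Channel | str,
    n_bins: int = DEFAULT_N_BINS,
) -> DensityVector:
    """Bin the unmasked pixels of a channel plane into a density vector.

    Parameters
    ----------
    plane
        2-D array of channel values (from :func:`~bgaudit.colorspace.select_channel`).
    mask
        Exclusion mask (True = drop pixel), or None for no exclusion.
    channel
        Which channel the plane holds; fixes the binning range.
    n_bins
        Number of equal-width bins (default 30).

    Raises
    ------
    EmptyHistogramError
        If no pixel survives the mask — never silently returns zeros.
    """
    channel = Channel(channel)
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError(f"plane must be 2-D, got shape {plane.shape}")
    if mask is None:
        values = plane.ravel()
    else:
        m = mask.mask if isinstance(mask, ObfuscationMask) else np.asarray(mask, bool)
        if m.shape != plane.shape:
            raise ValueError(f"mask shape {m.shape} != plane shape {plane.shape}")
        values = plane[~m]
    if values.size == 0:
        raise EmptyHistogramError("all pixels masked: empty histogram")
    counts, _ = np.histogram(values, bins=n_bins, range=channel.range)
    return DensityVector(
        density=counts / values.size, channel=channel, n_pixels_used=values.size
    )


def image_density(
    pixels: np.ndarray,
    mask: ObfuscationMask | np.ndarray | None,
    channel: Channel | str,
    n_bins: int = DEFAULT_N_BINS,
) -> DensityVector:
    """Convenience: channel selection + histogram in one call."""
    plane = select_channel(pixels, channel)
    return channel_histogram(plane, mask, channel, n_bins)


def densities_to_matrix(densities: list[DensityVector]) -> np.ndarray:
    """Stack density vectors into an (n_samples, n_bins) matrix."""
    return np.vstack([d.density for d in densities])
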