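"""Annotated microscopy image container.

An :class:`AnnotatedImage` bundles an 8-bit RGB raster with the axis-aligned
bounding boxes of the annotated leukocytes and a binary class label
(0 = healthy, 1 = sick).  Boxes use 0-based, half-open pixel coordinates
``(x0, y0, x1, y1)`` so that box area is ``(x1 - x0) * (y1 - y0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Box = tuple[int, int, int, int]


@dataclass
class AnnotatedImage:
    """8-bit RGB raster with leukocyte bounding boxes and a class label.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array of RGB intensities.
    boxes
        Leukocyte bounding boxes, 0-based half-open ``(x0, y0, x1, y1)``.
    label
        0 for healthy, 1 for sick.
    id
        Unique image identifier.
    """

    pixels: np.ndarray
    boxes: list[Box] = field(default_factory=list)
    label: int = 0
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must be (H, W, 3), got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        h, w = self.shape
        for box in self.boxes:
            validate_box(box, h, w)
        self.boxes = [tuple(int(c) for c in b) for b in self.boxes]

    @property
    def shape(self) -> tuple[int, int]:
        """Image height and width in pixels."""
        return self.pixels.shape[0], self.pixels.shape[1]

    def copy(self) -> "AnnotatedImage":
        return AnnotatedImage(
            pixels=self.pixels.copy(),
            boxes=list(self.boxes),
            label=self.label,
            id=self.id,
        )


def validate_box(box: Box, height: int, width: int) -> None:
    """Check that a half-open box is well formed and inside the raster."""
    if len(box) != 4:
        raise ValueError(f"box must have 4 coordinates, got {box!r}")
    x0, y0, x1, y1 = box
    if not (x0 < x1 and y0 < y1):
        raise ValueError(f"degenerate box {box!r}: need x0 < x1 and y0 < y1")
    if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
        raise ValueError(
            f"box {box!r} outside {height}x{width} image bounds"
        )
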