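"""Dataset persistence: image directories with annotation sidecars.

A dataset directory holds one raster per image (PNG/TIFF/JPEG/BMP), an
``annotations.csv`` sidecar with columns ``id,label,x0,y0,x1,y1`` (one
row per bounding box, 0-based half-open; box fields empty for an image
with no boxes), and optionally a ``spec.yaml`` recording the synthetic
generator parameters.  ALL-IDB2-style file names ``ImXXX_Y.*`` — where
the trailing ``Y`` encodes the label — are understood as a fallback when
an image has no CSV row, but an explicit CSV label always wins.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .colorspace import Channel
from .image import AnnotatedImage
from .synthetic import SyntheticSpec

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")
_ALLIDB_NAME = re.compile(r"^Im\d+_([01])$", re.IGNORECASE)


def save_dataset(
    images: list[AnnotatedImage],
    directory: str | Path,
    spec: SyntheticSpec | None = None,
    image_format: str = "png",
) -> Path:
    """Write rasters, the annotation CSV, and (optionally) the spec."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "annotations.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "x0", "y0", "x1", "y1"])
        for img in images:
            Image.fromarray(img.pixels).save(
                directory / f"{img.id}.{image_format}"
            )
            if img.boxes:
                for box in img.boxes:
                    writer.writerow([img.id, img.label, *box])
            else:
                writer.writerow([img.id, img.label, "", "", "", ""])
    if spec is not None:
        with open(directory / "spec.yaml", "w") as fh:
            yaml.safe_dump(spec.to_dict(), fh)
    return directory


def _read_annotations(path: Path) -> tuple[dict, dict]:
    labels: dict[str, int] = {}
    boxes: dict[str, list] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            image_id = row["id"]
            label = int(row["label"])
            if labels.get(image_id, label) != label:
                raise ValueError(f"conflicting labels for image {image_id!r}")
            labels[image_id] = label
            boxes.setdefault(image_id, [])
            if row["x0"] != "":
                boxes[image_id].append(
                    (int(row["x0"]), int(row["y0"]), int(row["x1"]), int(row["y1"]))
                )
    return labels, boxes


def load_dataset(directory: str | Path) -> list[AnnotatedImage]:
    """Load every raster in a directory with its label and boxes.

    Labels come from ``annotations.csv`` when present; otherwise from the
    ALL-IDB2 file-name convention.  An image with neither is an error, as
    is a label outside {0, 1}.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not paths:
        raise FileNotFoundError(f"no images found in {directory}")
    ann_path = directory / "annotations.csv"
    labels, boxes = _read_annotations(ann_path) if ann_path.exists() else ({}, {})

    images = []
    for path in paths:
        image_id = path.stem
        label = labels.get(image_id)
        if label is None:
            m = _ALLIDB_NAME.match(image_id)
            if m is None:
                raise ValueError(
                    f"image {image_id!r} has no annotation row and no "
                    "parseable label in its file name"
                )
            label = int(m.group(1))
        if label not in (0, 1):
            raise ValueError(f"image {image_id!r}: label must be 0 or 1")
        pixels = np.asarray(Image.open(path).convert("RGB"))
        images.append(
            AnnotatedImage(
                pixels=pixels,
                boxes=boxes.get(image_id, []),
                label=label,
                id=image_id,
            )
        )
    return images


def load_spec(directory: str | Path) -> SyntheticSpec:
    with open(Path(directory) / "spec.yaml") as fh:
        return SyntheticSpec.from_dict(yaml.safe_load(fh))


def save_density_table(
    path: str | Path,
    ids: list[str],
    labels,
    channel,
    densities: np.ndarray,
) -> Path:
    """One row per image: id, label, channel, then the bin densities."""
    path = Path(path)
    densities = np.atleast_2d(np.asarray(densities, dtype=np.float64))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        n_bins = densities.shape[1]
        writer.writerow(
            ["id", "label", "channel"] + [f"bin_{i}" for i in range(n_bins)]
        )
        for image_id, label, row in zip(ids, labels, densities, strict=True):
            writer.writerow(
                [image_id, int(label), Channel(channel).value] + [f"{v:.8f}" for v in row]
            )
    return path


def save_entropy_table(
    path: str | Path,
    ids: list[str],
    labels,
    channel,
    obfuscated: bool,
    entropies,
) -> Path:
    """One row per image: id, label, channel, obfuscated, entropy."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "channel", "obfuscated", "entropy"])
        for image_id, label, h in zip(ids, labels, entropies, strict=True):
            writer.writerow([image_id, int(label), Channel(channel).value, obfuscated, f"{h:.8f}"])
    return path


def require_boxes(images: list[AnnotatedImage]) -> None:
    """Fail with the offending ids if any image lacks a bounding box."""
    missing = [img.id for img in images if not img.boxes]
    if missing:
        raise ValueError(
            "obfuscation requested but these images have no boxes: "
            + ", ".join(missing)
        )
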