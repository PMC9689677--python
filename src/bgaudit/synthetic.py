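"""Synthetic blood-smear-like image generator.

Emulates the structure of a single-cell leukocyte crop benchmark: a
balanced two-class set of small RGB images, each holding one dominant,
roughly central stained-lymphocyte blob (annotated with a tight bounding
box), a scatter of pale erythrocyte-like distractor disks (deliberately
*not* annotated), and a background field whose per-pixel hue is drawn
from a class-conditional wrapped (von Mises) distribution.

The class signal lives in the background: the two classes differ in hue
location and concentration, so background hue histograms separate the
classes while saturation/value ranges are shared.  Making the sick class
*less* concentrated also makes its background hue entropy higher, which
is the dispersion contrast the entropy classifier is meant to detect.

Geometry and staining are stylized, not photorealistic — see
docs/methods.md for what this generator does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .image import AnnotatedImage

HEALTHY, SICK = 0, 1


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic two-class smear dataset.

    Hue parameters are per class: ``(mean_deg, concentration)`` of a von
    Mises distribution on the hue circle (concentration ``inf`` collapses
    to the mean).  Saturation/value ranges are 8-bit ``(lo, hi)`` bounds.
    Defaults give the two backgrounds hue means 60° apart with the sick
    class more dispersed.
    """

    image_height: int = 128
    image_width: int = 128
    n_per_class: int = 130
    background_hue_params: dict = field(
        default_factory=lambda: {HEALTHY: (330.0, 10.0), SICK: (270.0, 4.0)}
    )
    background_sat_range: dict = field(
        default_factory=lambda: {HEALTHY: (40, 110), SICK: (40, 110)}
    )
    background_val_range: dict = field(
        default_factory=lambda: {HEALTHY: (150, 230), SICK: (150, 230)}
    )
    background_hue_jitter: dict = field(
        default_factory=lambda: {HEALTHY: 0.0, SICK: 0.0}
    )
    cell_radius_range: tuple = (18, 30)
    cell_hue_deg: float = 280.0
    distractor_count_range: tuple = (3, 8)
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image_height/image_width: dimensions must be >= 32x32")
        if self.n_per_class < 1:
            raise ValueError("n_per_class: must be >= 1")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi) or hi >= min(self.image_height, self.image_width) / 2:
            raise ValueError(
                "cell_radius_range: need 0 < lo <= hi < min(H, W)/2"
            )
        for cls in (HEALTHY, SICK):
            mean_deg, kappa = self.background_hue_params[cls]
            if not (0 <= mean_deg < 360):
                raise ValueError("background_hue_params: mean_deg must be in [0, 360)")
            if not kappa > 0:
                raise ValueError("background_hue_params: concentration must be > 0")
            if self.background_hue_jitter[cls] < 0:
                raise ValueError("background_hue_jitter: must be >= 0")
            for name, rng_ in (
                ("background_sat_range", self.background_sat_range[cls]),
                ("background_val_range", self.background_val_range[cls]),
            ):
                if not (0 <= rng_[0] <= rng_[1] <= 255):
                    raise ValueError(f"{name}: bounds must satisfy 0 <= lo <= hi <= 255")
        if not (0 <= self.cell_hue_deg < 360):
            raise ValueError("cell_hue_deg: must be in [0, 360)")
        dlo, dhi = self.distractor_count_range
        if not (0 <= dlo <= dhi):
            raise ValueError("distractor_count_range: need 0 <= lo <= hi")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma: must be >= 0")

    def to_dict(self) -> dict:
        return {
            "image_height": self.image_height,
            "image_width": self.image_width,
            "n_per_class": self.n_per_class,
            "background_hue_params": {
                int(k): list(v) for k, v in self.background_hue_params.items()
            },
            "background_sat_range": {
                int(k): list(v) for k, v in self.background_sat_range.items()
            },
            "background_val_range": {
                int(k): list(v) for k, v in self.background_val_range.items()
            },
            "background_hue_jitter": {
                int(k): float(v) for k, v in self.background_hue_jitter.items()
            },
            "cell_radius_range": list(self.cell_radius_range),
            "cell_hue_deg": self.cell_hue_deg,
            "distractor_count_range": list(self.distractor_count_range),
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for key in ("background_hue_params", "background_sat_range", "background_val_range"):
            d[key] = {int(k): tuple(v) for k, v in d[key].items()}
        if "background_hue_jitter" in d:
            d["background_hue_jitter"] = {
                int(k): float(v) for k, v in d["background_hue_jitter"].items()
            }
        for key in ("cell_radius_range", "distractor_count_range"):
            d[key] = tuple(d[key])
        return cls(**d)


def _sample_hue_deg(mean_deg, kappa, size, rng: np.random.Generator):
    """von Mises hue sample in degrees; kappa=inf degenerates to the mean."""
    if np.isinf(kappa):
        return np.full(size, mean_deg, dtype=np.float64)
    sample = rng.vonmises(np.radians(mean_deg - 180.0), kappa, size=size)
    return (np.degrees(sample) + 180.0) % 360.0


def _hsv_to_rgb8(h_deg, s_8bit, v_8bit) -> np.ndarray:
    hsv = np.stack(
        [np.asarray(h_deg) / 360.0,
         np.asarray(s_8bit) / 255.0,
         np.asarray(v_8bit) / 255.0],
        axis=-1,
    )
    return hsv_to_rgb(hsv) * 255.0


def _blob_mask(h, w, cy, cx, ry, rx, amps, phases) -> np.ndarray:
    """Filled ellipse with low-order Fourier boundary irregularity."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / ry, (xx - cx) / rx
    rho = np.sqrt(dy * dy + dx * dx)
    theta = np.arctan2(dy, dx)
    boundary = 1.0
    for k, (a, phi) in enumerate(zip(amps, phases), start=2):
        boundary = boundary + a * np.cos(k * theta + phi)
    return rho <= boundary


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def generate_image(
    spec: SyntheticSpec, label: int, rng: np.random.Generator, image_id: str = ""
) -> AnnotatedImage:
    """Render one labeled synthetic smear crop.

    Background hue is class-conditional von Mises; distractor disks are
    pale and red-toned (unannotated); the single lymphocyte blob is a
    darker, saturated purple ellipse with an irregular boundary, and its
    tight axis-aligned bounding box is the image's only annotation.
    Deterministic given the generator state.
    """
    if label not in (HEALTHY, SICK):
        raise ValueError(f"label must be 0 or 1, got {label}")
    spec.validate()
    h, w = spec.image_height, spec.image_width

    mean_deg, kappa = spec.background_hue_params[label]
    jitter = spec.background_hue_jitter[label]
    if jitter > 0:
        # per-image staining shift: the whole background hue mode moves
        mean_deg = (mean_deg + rng.normal(0.0, jitter)) % 360.0
    hue = _sample_hue_deg(mean_deg, kappa, (h, w), rng)
    slo, shi = spec.background_sat_range[label]
    vlo, vhi = spec.background_val_range[label]
    sat = rng.uniform(slo, shi, size=(h, w))
    val = rng.uniform(vlo, vhi, size=(h, w))
    img = _hsv_to_rgb8(hue, sat, val)

    # erythrocyte-like distractors: pale, low-saturation red disks
    n_distract = int(rng.integers(spec.distractor_count_range[0],
                                  spec.distractor_count_range[1] + 1))
    for _ in range(n_distract):
        r = rng.uniform(4, max(5.0, min(h, w) / 10))
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        mask = _blob_mask(h, w, cy, cx, r, r, [rng.uniform(0, 0.08)],
                          [rng.uniform(0, 2 * np.pi)])
        if not mask.any():
            continue
        d_hue = rng.uniform(-12.0, 12.0) % 360.0
        d_sat = rng.uniform(25, 60)
        d_val = rng.uniform(190, 235)
        img[mask] = _hsv_to_rgb8(d_hue, d_sat, d_val)

    # the lymphocyte blob: central-ish, saturated purple, irregular edge
    r = rng.uniform(*spec.cell_radius_range)
    cy = h / 2 + rng.uniform(-0.1, 0.1) * h
    cx = w / 2 + rng.uniform(-0.1, 0.1) * w
    ry = r * rng.uniform(0.85, 1.15)
    rx = r * rng.uniform(0.85, 1.15)
    amps = rng.uniform(0.0, 0.08, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    cell_mask = _blob_mask(h, w, cy, cx, ry, rx, amps, phases)
    c_hue = (spec.cell_hue_deg + rng.uniform(-5, 5)) % 360.0
    img[cell_mask] = _hsv_to_rgb8(c_hue, rng.uniform(150, 210),
                                  rng.uniform(90, 150))
    box = _tight_bbox(cell_mask)

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return AnnotatedImage(pixels=pixels, boxes=[box], label=label, id=image_id)


def generate_dataset(spec: SyntheticSpec) -> list[AnnotatedImage]:
    """Generate the full balanced dataset: 2·n_per_class images.

    Each image draws from its own counter-derived substream of the
    dataset seed, so any image is reproducible independently of the rest.
    """
    spec.validate()
    images: list[AnnotatedImage] = []
    names = {HEALTHY: "healthy", SICK: "sick"}
    for label in (HEALTHY, SICK):
        for i in range(spec.n_per_class):
            rng = np.random.default_rng([spec.seed, label, i])
            images.append(
                generate_image(spec, label, rng, image_id=f"{names[label]}_{i:04d}")
            )
    return images
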