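"""Generate the balanced synthetic smear dataset used by the later steps.

Renders 260 images (130 healthy / 130 sick) at the default class
contrast — hue means 60° apart, the sick background more dispersed —
and writes rasters + annotation CSV + generator spec under
scratch/synthetic_smears/.  Later steps regenerate in memory from the
same spec, so this step mainly documents what the data look like on disk.
"""

import argparse
from collections import Counter
from pathlib import Path

from bgaudit.io import save_dataset
from bgaudit.synthetic import SyntheticSpec, generate_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument(
        "--out", type=Path, default=Path("scratch/synthetic_smears")
    )
    args = parser.parse_args()

    spec = SyntheticSpec(seed=args.seed)
    images = generate_dataset(spec)
    save_dataset(images, args.out, spec=spec)

    counts = Counter(img.label for img in images)
    print(f"wrote {len(images)} images to {args.out}")
    print(f"  healthy: {counts[0]}   sick: {counts[1]}")
    print(f"  image size: {spec.image_height}x{spec.image_width}")
    print(
        "  background hue (mean°, concentration): "
        f"healthy {spec.background_hue_params[0]}, "
        f"sick {spec.background_hue_params[1]}"
    )


if __name__ == "__main__":
    main()
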