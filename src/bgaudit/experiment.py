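"""Full evaluation grid: channel × obfuscation × augmentation × classifier.

Every grid cell is scored by repeated random 2/3-train / 1/3-test splits
(30 by default) and the metrics averaged over repeats.  Splits are
regenerated from ``base_seed + repeat`` and shared across all grid cells
of a repeat, so the obfuscated-vs-unmodified contrast for a cell is a
paired comparison, not split noise.  Per-repeat values are retained next
to the averages so dispersion is always available.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines
from . import divergence as dv
from .colorspace import Channel, rgb_to_hsv
from .entropy import EntropyClassifier, entropy_features
from .image import AnnotatedImage
from .io import require_boxes
from .metrics import compute_metrics
from .preprocess import AugmentationSpec, preprocess_pipeline
from .vectorize import DEFAULT_N_BINS, channel_histogram

CLASSIFIERS = ("cross_entropy", "mse", "shannon_logreg", "xgboost", "logreg")


@dataclass
class ExperimentConfig:
    channels: list = field(default_factory=lambda: [Channel.H])
    obfuscate: list = field(default_factory=lambda: [False, True])
    augmentations: list = field(default_factory=lambda: [AugmentationSpec()])
    classifiers: list = field(default_factory=lambda: list(CLASSIFIERS))
    n_repeats: int = 30
    train_fraction: float = 2.0 / 3.0
    n_bins: int = DEFAULT_N_BINS
    base_seed: int = 0

    def __post_init__(self) -> None:
        self.channels = [Channel(c) for c in self.channels]
        for clf in self.classifiers:
            if clf not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {clf!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ResultsTable:
    """Averaged grid results plus the per-repeat records behind them."""

    summary: pd.DataFrame
    per_repeat: pd.DataFrame
    config: ExperimentConfig


def vectorize_images(
    images: list[AnnotatedImage],
    channels: list,
    aug: AugmentationSpec,
    obfuscate_flag: bool,
    n_bins: int = DEFAULT_N_BINS,
    base_seed: int = 0,
    condition_index: int = 0,
) -> dict:
    """Preprocess every image once and bin it per channel.

    Returns ``{channel: (n_images, n_bins) density matrix}``.  The noise
    augmentation draws from a substream keyed by (base_seed, condition,
    image index), so conditions are independent and reproducible.
    """
    channels = [Channel(c) for c in channels]
    if obfuscate_flag:
        require_boxes(images)
    matrices = {c: np.empty((len(images), n_bins)) for c in channels}
    for i, image in enumerate(images):
        rng = np.random.default_rng([base_seed, 1000 + condition_index, i])
        processed, mask = preprocess_pipeline(image, aug, obfuscate_flag, rng)
        hsv = rgb_to_hsv(processed.pixels) if any(c.needs_hsv for c in channels) else None
        for c in channels:
            if c.needs_hsv:
                plane = hsv[..., "HSV".index(c.value)]
            else:
                plane = processed.pixels[..., "RGB".index(c.value)].astype(np.float64)
            matrices[c][i] = channel_histogram(plane, mask, c, n_bins).density
    return matrices


def _classify_cell(
    classifier: str,
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
) -> np.ndarray:
    Xtr, Xte = X[train_idx], X[test_idx]
    ytr = y[train_idx]
    if classifier in ("cross_entropy", "mse"):
        model = dv.fit(Xtr, ytr, divergence=classifier)
        return dv.predict(model, Xte)
    if classifier == "shannon_logreg":
        clf = EntropyClassifier().fit(entropy_features(Xtr), ytr)
        return clf.predict(entropy_features(Xte))
    kind = "xgboost" if classifier == "xgboost" else "logistic_regression"
    return baselines.fit_predict(kind, Xtr, ytr, Xte, seed=seed)


def run_experiment(images: list[AnnotatedImage], config: ExperimentConfig) -> ResultsTable:
    """Run the whole grid and average metrics over repeated splits.

    A failing grid cell is recorded (``error`` column) without aborting
    the remaining cells.
    """
    labels = np.array([img.label for img in images])
    n = len(images)
    split_cache = {
        r: dv.split(n, dv.SplitSpec(config.train_fraction, seed=config.base_seed + r))
        for r in range(config.n_repeats)
    }

    records: list[dict] = []
    conditions = list(product(config.augmentations, config.obfuscate))
    for cond_idx, (aug, obf) in enumerate(conditions):
        try:
            matrices = vectorize_images(
                images, config.channels, aug, obf,
                n_bins=config.n_bins, base_seed=config.base_seed,
                condition_index=cond_idx,
            )
        except Exception as exc:  # noqa: BLE001 — fail the condition, not the run
            print(
                f"condition failed: obfuscated={obf} aug={aug.describe()} -> {exc}",
                file=sys.stderr,
            )
            for channel in config.channels:
                for classifier in config.classifiers:
                    records.append({
                        "obfuscated": obf,
                        "channel": channel.value,
                        "augmentation": aug.describe(),
                        "classifier": classifier,
                        "repeat": -1,
                        "accuracy": np.nan,
                        "f1_healthy": np.nan,
                        "f1_sick": np.nan,
                        "error": str(exc),
                    })
            continue
        for channel in config.channels:
            X = matrices[channel]
            for classifier in config.classifiers:
                for r, (train_idx, test_idx) in split_cache.items():
                    base = {
                        "obfuscated": obf,
                        "channel": channel.value,
                        "augmentation": aug.describe(),
                        "classifier": classifier,
                        "repeat": r,
                    }
                    try:
                        pred = _classify_cell(
                            classifier, X, labels, train_idx, test_idx,
                            seed=config.base_seed + r,
                        )
                        report = compute_metrics(labels[test_idx], pred)
                        records.append(
                            base | {
                                "accuracy": report.accuracy,
                                "f1_healthy": report.healthy.f1,
                                "f1_sick": report.sick.f1,
                                "error": "",
                            }
                        )
                    except Exception as exc:  # noqa: BLE001 — isolate the cell
                        print(
                            f"cell failed: {base} -> {exc}", file=sys.stderr
                        )
                        records.append(
                            base | {
                                "accuracy": np.nan,
                                "f1_healthy": np.nan,
                                "f1_sick": np.nan,
                                "error": str(exc),
                            }
                        )

    per_repeat = pd.DataFrame.from_records(records)
    keys = ["obfuscated", "channel", "augmentation", "classifier"]
    grouped = per_repeat.groupby(keys, sort=False)
    summary = grouped.agg(
        accuracy=("accuracy", "mean"),
        accuracy_std=("accuracy", "std"),
        f1_healthy=("f1_healthy", "mean"),
        f1_sick=("f1_sick", "mean"),
        n_repeats=("repeat", "count"),
        n_errors=("error", lambda e: int((e != "").sum())),
    ).reset_index()
    summary["base_seed"] = config.base_seed
    return ResultsTable(summary=summary, per_repeat=per_repeat, config=config)


def report(results: ResultsTable, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write the averaged table as CSV and a fixed-format markdown table."""
    if results.summary.empty:
        raise ValueError("empty results table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    md_path = out_dir / f"{stem}.md"
    results.summary.to_csv(csv_path, index=False, float_format="%.6f")
    results.per_repeat.to_csv(
        out_dir / f"{stem}_per_repeat.csv", index=False, float_format="%.6f"
    )
    md_path.write_text(_markdown_table(results.summary))
    return {"csv": csv_path, "markdown": md_path}


def _markdown_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = [
            f"{v:.3f}" if isinstance(v, float) else str(v) for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
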