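"""Shannon entropy of density vectors and the entropy-only classifier.

Entropy, H(P) = −Σ Pᵢ log Pᵢ, measures how evenly a channel's pixel
values spread over the histogram bins: a one-hot distribution has
entropy 0, the uniform distribution log(n_bins).  Used as the *sole*
feature of a one-dimensional logistic regression, it tests whether the
mere dispersion of background color separates healthy from sick.

The default reporting scale is ``normalized`` — nats divided by
log(n_bins) — so values are comparable across bin counts and lie in
[0, 1]; raw ``nats`` are available via the ``scale`` argument.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

from .vectorize import DensityVector

SCALES = ("nats", "normalized")


def shannon_entropy(p, scale: str = "nats") -> float:
    """H(P) = −Σ Pᵢ log Pᵢ with 0·log 0 ≡ 0.

    ``scale='normalized'`` divides by log(n_bins), mapping onto [0, 1].
    """
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}")
    arr = p.density if isinstance(p, DensityVector) else np.asarray(p, np.float64)
    if abs(arr.sum() - 1.0) > 1e-9 or np.any(arr < 0):
        raise ValueError("input must be a normalized density")
    pos = arr[arr > 0]
    h = float(-np.sum(pos * np.log(pos)))
    if scale == "normalized":
        h /= np.log(arr.shape[0])
    return h


class EntropyClassifier:
    """Logistic regression on the single entropy feature."""

    def __init__(self, scale: str = "normalized"):
        self.scale = scale
        self._lr: LogisticRegression | None = None

    def fit(self, entropies, labels) -> "EntropyClassifier":
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        x = np.asarray(entropies, dtype=np.float64).reshape(-1, 1)
        self._lr = LogisticRegression()
        self._lr.fit(x, y)
        return self

    def predict(self, entropies) -> np.ndarray:
        if self._lr is None:
            raise ValueError("classifier is not fitted")
        x = np.asarray(entropies, dtype=np.float64).reshape(-1, 1)
        return self._lr.predict(x).astype(int)

    @property
    def coef_(self) -> tuple[float, float]:
        """(weight, bias) of the fitted one-feature model."""
        if self._lr is None:
            raise ValueError("classifier is not fitted")
        return float(self._lr.coef_[0, 0]), float(self._lr.intercept_[0])


def entropy_features(densities, scale: str = "normalized") -> np.ndarray:
    """Entropy of each density vector, as a 1-D feature array."""
    return np.array([shannon_entropy(d, scale) for d in densities])


def class_entropy_summary(entropies, labels) -> dict[str, float]:
    """Mean and std of entropy per class (population std)."""
    h = np.asarray(entropies, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    return {
        "avg_entropy_healthy": float(h[y == 0].mean()),
        "std_entropy_healthy": float(h[y == 0].std()),
        "avg_entropy_sick": float(h[y == 1].mean()),
        "std_entropy_sick": float(h[y == 1].std()),
    }
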