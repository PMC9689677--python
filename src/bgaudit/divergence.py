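"""Divergence-to-representative classifier.

Training averages the density vectors of each class into representative
distributions M0 (healthy) and M1 (sick), then records the mean and
standard deviation of each representative's divergence over the *whole*
training set.  A test sample is assigned to the class whose z-normalized
divergence is smaller, with ties going to class 0:

    predict 1  iff  (d(x, M1) − m1)/s1  <  (d(x, M0) − m0)/s0

Two divergences are supported: cross-entropy H(P, Q) = −Σ Pᵢ log Qᵢ
(natural log, asymmetric — the sample is always P) and the summed squared
error MSE(P, Q) = Σ (Pᵢ − Qᵢ)².  The log base only rescales divergences
and is absorbed by the z-normalization, so predictions are base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .vectorize import DensityVector

#: guard added inside the log so empty histogram bins do not produce −inf
DEFAULT_EPSILON = 1e-12

DIVERGENCES = ("cross_entropy", "mse")


class FittingError(ValueError):
    """Raised when the training set cannot support a valid model."""


def _as_matrix(densities) -> np.ndarray:
    if isinstance(densities, np.ndarray):
        return np.atleast_2d(np.asarray(densities, dtype=np.float64))
    rows = [
        d.density if isinstance(d, DensityVector) else np.asarray(d, np.float64)
        for d in densities
    ]
    return np.vstack(rows)


def cross_entropy(p, q, epsilon: float = DEFAULT_EPSILON) -> float:
    """−Σ pᵢ·log(qᵢ + ε), natural log.  Asymmetric in (p, q)."""
    p = p.density if isinstance(p, DensityVector) else np.asarray(p, np.float64)
    q = q.density if isinstance(q, DensityVector) else np.asarray(q, np.float64)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    return float(-np.sum(p * np.log(q + epsilon)))


def mse(p, q) -> float:
    """Σ (pᵢ − qᵢ)² — a plain sum of squared differences, symmetric."""
    p = p.density if isinstance(p, DensityVector) else np.asarray(p, np.float64)
    q = q.density if isinstance(q, DensityVector) else np.asarray(q, np.float64)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    return float(np.sum((p - q) ** 2))


@dataclass
class SplitSpec:
    """Random 2/3 train / 1/3 test split specification."""

    train_fraction: float = 2.0 / 3.0
    seed: int = 0


def split(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle indices; first ⌊train_fraction·n⌋ train, rest test."""
    if n < 3:
        raise ValueError(f"need n >= 3 to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    s = int(np.floor(spec.train_fraction * n))
    return perm[:s], perm[s:]


@dataclass
class DivergenceModel:
    """Fitted representative distributions plus divergence statistics."""

    M0: np.ndarray
    M1: np.ndarray
    m0: float
    s0: float
    m1: float
    s1: float
    divergence: str
    epsilon: float = DEFAULT_EPSILON

    def _divergence_fn(self):
        if self.divergence == "cross_entropy":
            return lambda p, q: cross_entropy(p, q, self.epsilon)
        return mse

    def to_json(self) -> str:
        return json.dumps(
            {
                "M0": self.M0.tolist(),
                "M1": self.M1.tolist(),
                "m0": self.m0,
                "s0": self.s0,
                "m1": self.m1,
                "s1": self.s1,
                "divergence": self.divergence,
                "epsilon": self.epsilon,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DivergenceModel":
        d = json.loads(text)
        return cls(
            M0=np.asarray(d["M0"]),
            M1=np.asarray(d["M1"]),
            m0=d["m0"],
            s0=d["s0"],
            m1=d["m1"],
            s1=d["s1"],
            divergence=d["divergence"],
            epsilon=d["epsilon"],
        )


def fit(
    train_densities,
    train_labels,
    divergence: str = "mse",
    epsilon: float = DEFAULT_EPSILON,
    per_class_stats: bool = False,
) -> DivergenceModel:
    """Fit representatives and divergence statistics on a training set.

    ``per_class_stats=False`` (the default) pools divergences over the
    whole training set when computing (m0, s0) and (m1, s1); setting it
    True restricts each pool to the matching class's samples instead.
    Standard deviations use the population convention (divide by n).

    Raises
    ------
    FittingError
        If a class is absent, has fewer than 2 samples, or a divergence
        pool has zero spread (z-normalization would divide by zero).
    """
    if divergence not in DIVERGENCES:
        raise ValueError(f"divergence must be one of {DIVERGENCES}")
    X = _as_matrix(train_densities)
    y = np.asarray(train_labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("densities and labels differ in length")
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise FittingError(f"need >= 2 training samples of class {cls}")

    M0 = X[y == 0].mean(axis=0)
    M1 = X[y == 1].mean(axis=0)
    # bin-wise means of unit-sum rows; renormalize away float drift
    M0 = M0 / M0.sum()
    M1 = M1 / M1.sum()

    fn = (
        (lambda p, q: cross_entropy(p, q, epsilon))
        if divergence == "cross_entropy"
        else mse
    )
    pool0 = X[y == 0] if per_class_stats else X
    pool1 = X[y == 1] if per_class_stats else X
    D0 = np.array([fn(row, M0) for row in pool0])
    D1 = np.array([fn(row, M1) for row in pool1])
    m0, s0 = float(D0.mean()), float(D0.std())
    m1, s1 = float(D1.mean()), float(D1.std())
    if s0 <= 0 or s1 <= 0:
        raise FittingError(
            "zero spread in training divergences; cannot z-normalize"
        )
    return DivergenceModel(
        M0=M0, M1=M1, m0=m0, s0=s0, m1=m1, s1=s1,
        divergence=divergence, epsilon=epsilon,
    )


def predict(model: DivergenceModel, densities) -> np.ndarray:
    """Classify samples by smaller z-normalized divergence (ties → 0)."""
    X = _as_matrix(densities)
    fn = model._divergence_fn()
    dt0 = np.array([(fn(row, model.M0) - model.m0) / model.s0 for row in X])
    dt1 = np.array([(fn(row, model.M1) - model.m1) / model.s1 for row in X])
    return (dt1 < dt0).astype(int)
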