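"""Seed-controlled ML baselines on raw density vectors.

Gradient-boosted trees (XGBoost) and logistic regression consume the
30-dimensional channel density directly.  Hyperparameters are library
defaults, snapshotted via :func:`hyperparameters` so each results file
can record exactly what was run.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

KINDS = ("xgboost", "logistic_regression")


def make_model(kind: str, seed: int = 0):
    if kind == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    if kind == "logistic_regression":
        # lbfgs is deterministic; max_iter raised so small-n fits converge
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")


def fit_predict(
    kind: str,
    train_densities: np.ndarray,
    train_labels,
    test_densities: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Train a baseline with library defaults and predict the test set."""
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = make_model(kind, seed)
    model.fit(np.asarray(train_densities, np.float64), y)
    return model.predict(np.asarray(test_densities, np.float64)).astype(int)


def hyperparameters(kind: str, seed: int = 0) -> dict:
    """The exact hyperparameter map a fit with this seed would use."""
    return {k: v for k, v in make_model(kind, seed).get_params().items()
            if v is not None}
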