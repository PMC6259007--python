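"""Node predictability: shared variance of each symptom with all others.

Predictability of node i is the in-sample coefficient of determination R^2
of the least-squares regression of item i on the remaining items.  It is an
absolute measure of interconnectedness: under a Gaussian graphical model
with precision K and covariance Sigma the population value is

    R^2_i = 1 - 1 / (Sigma_ii * K_ii),

which the sample estimate approaches at large n.  Items are treated on
their common 0-4 severity scale, so the linear (Gaussian) nodewise model is
used throughout.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import SymptomDataset, ValidationError

__all__ = ["node_predictability", "predictability", "mean_predictability"]


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, SymptomDataset):
        return data.scores.astype(float), list(data.items)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValidationError("data must be a 2-D case-by-item matrix")
    return X, [f"V{i + 1}" for i in range(X.shape[1])]


def _r2(X: np.ndarray, i: int, ridge: float = 0.0) -> float:
    y = X[:, i]
    Z = np.delete(X, i, axis=1)
    Z = np.column_stack([np.ones(len(Z)), Z])
    if ridge > 0.0:
        A = Z.T @ Z + ridge * np.eye(Z.shape[1])
        A[0, 0] -= ridge  # leave the intercept unpenalized
        beta = np.linalg.solve(A, Z.T @ y)
    else:
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValidationError(
                "singular design (collinear predictors); pass ridge > 0 to "
                "regularize the nodewise regression"
            )
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValidationError("response item has zero variance")
    r2 = 1.0 - np.sum(resid**2) / sst
    return float(min(max(r2, 0.0), 1.0))


def node_predictability(data, node: str | int, ridge: float = 0.0) -> float:
    """R^2 of one node regressed on all remaining nodes (in-sample)."""
    X, labels = _as_matrix(data)
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("need n_cases > n_items for nodewise regression")
    i = node if isinstance(node, (int, np.integer)) else labels.index(node)
    return _r2(X, int(i), ridge=ridge)


def predictability(data, ridge: float = 0.0) -> pd.Series:
    """Per-node predictability R^2 for every node, as a labelled series."""
    X, labels = _as_matrix(data)
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("need n_cases > n_items for nodewise regression")
    vals = [_r2(X, i, ridge=ridge) for i in range(X.shape[1])]
    s = pd.Series(vals, index=labels, name="predictability")
    s.index.name = "node"
    return s


def mean_predictability(data, ridge: float = 0.0) -> float:
    """Arithmetic mean of the per-node R^2 values."""
    return float(predictability(data, ridge=ridge).mean())
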