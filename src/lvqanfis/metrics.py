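"""Evaluation arithmetic: RMSE, coefficient of determination, fold splitting."""

from __future__ import annotations

import numpy as np


def rmse(actual, predicted) -> float:
    """Root mean square error, sqrt(sum((a - p)^2) / N)."""
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length, nonempty")
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r_squared(actual, predicted) -> float:
    """Coefficient of determination, 1 - SSE/SST with SST about mean(actual).

    Negative values (worse-than-mean predictors) are reported, not clipped.
    """
    a = np.asarray(actual, float)
    p = np.asarray(predicted, float)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length, nonempty")
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined: actual values are constant")
    sse = float(np.sum((a - p) ** 2))
    return 1.0 - sse / sst


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle then contiguous chunking into k folds.

    Fold sizes differ by at most one; the folds partition range(n).
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, k)]
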