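"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean along the last axis.

    Windows shrink at the boundaries so every output position is the exact
    mean of the available values (no padding with edge replicates). With
    ``window >=`` the axis length this collapses to the full-axis mean.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n == 0:
        return x.copy()
    half = (window - 1) // 2
    c = np.zeros(x.shape[:-1] + (n + 1,), dtype=float)
    np.cumsum(x, axis=-1, out=c[..., 1:])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (window - half), n)  # exclusive
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def check_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator from a seed, passing Generators through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def condensed_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Index of unordered pair (i<j) in the row-major upper-triangle order."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return lo * (2 * n - lo - 1) // 2 + (hi - lo - 1)
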