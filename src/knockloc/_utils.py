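"""Small shared helpers (RNG coercion, column standardization)."""

from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent integer seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return np.array(
        [int(c.generate_state(1)[0]) % MAX_SEED for c in ss.spawn(n)], dtype=np.int64
    )


def standardize_columns(X: np.ndarray, ddof: int = 0):
    """Return (X standardized to mean 0 / unit variance, keep-mask).

    Zero-variance columns cannot be standardized; they are zeroed out and
    flagged False in the mask so callers can drop or ignore them.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    keep = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, keep
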