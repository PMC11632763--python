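"""Discretized SMOTE oversampling for integer count descriptors.

The variant implemented here draws two distinct random rows from the
minority class, interpolates uniformly along the segment between them,
and rounds the result so synthetic rows live on the same integer count
lattice as real ones.  Pair selection is uniformly random over minority
rows — not k-nearest-neighbour as in classical SMOTE.  Oversampling is
pure: majority rows are never removed, and balancing is only ever
applied to training data, never to validation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BalanceConfig", "smote_discrete", "balance_training_set"]


@dataclass
class BalanceConfig:
    """Settings for class balancing.

    ``target`` is always "equalize" (synthesize minority rows until the
    classes have equal counts); ``rounding`` is half-away-from-zero,
    which on the non-negative count lattice is ordinary half-up.
    """

    target: str = "equalize"
    rounding: str = "half-up"
    seed: int = 0


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds halves to even; counts are non-negative so
    # floor(x + 0.5) is half-away-from-zero
    return np.floor(x + 0.5).astype(np.int64)


def smote_discrete(
    minority_rows: np.ndarray,
    n_synthetic: int,
    config: BalanceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate ``n_synthetic`` integer rows by rounded pairwise interpolation.

    Each synthetic row is ``round(a + t * (b - a))`` for two distinct
    uniformly chosen minority rows ``a``, ``b`` and ``t ~ Uniform(0, 1)``
    (endpoints allowed, so exact copies can occur).  Every coordinate of
    a synthetic row therefore lies within the coordinate-wise bounds of
    its two parents.
    """
    minority_rows = np.asarray(minority_rows)
    if minority_rows.ndim != 2 or minority_rows.shape[0] < 2:
        raise ValueError("need at least 2 minority rows")
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed if config else 0)
    n = minority_rows.shape[0]
    out = np.empty((n_synthetic, minority_rows.shape[1]), dtype=np.int64)
    for s in range(n_synthetic):
        i = rng.integers(n)
        j = rng.integers(n - 1)
        if j >= i:
            j += 1
        t = rng.uniform()
        a = minority_rows[i].astype(float)
        b = minority_rows[j].astype(float)
        out[s] = _round_half_up(a + t * (b - a))
    return out


def balance_training_set(
    X: np.ndarray,
    y: np.ndarray,
    config: BalanceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equalize class counts by synthesizing minority rows.

    Returns ``(X_out, y_out, synthetic_flag)``: the original rows appear
    unmodified as a prefix (in their input order), synthetic rows are
    appended and flagged True.  Already-balanced input is returned
    unchanged with zero synthetic rows.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if len(classes) != 2:
        raise ValueError("binary labels expected")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X, y, np.zeros(len(y), dtype=bool)
    synth = smote_discrete(X[y == minority], n_needed, config=config, rng=rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    flag = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(n_needed, dtype=bool)])
    return X_out, y_out, flag
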