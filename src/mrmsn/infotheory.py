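"""Discrete information-theoretic estimators on discretized expression data.

All estimators are plug-in (maximum-likelihood) estimates on the empirical
distribution of integer symbol vectors, with entropies in bits (log base 2).
Continuous expression values are first reduced to symbols by per-gene
equal-frequency (quantile) binning; everything downstream — entropy,
conditional entropy, mutual information, and the pairwise mutual-information
matrix (MIM) — operates on those symbols.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "discretize",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "build_mim",
    "default_bins",
]


def default_bins(n_samples: int) -> int:
    """Default bin count for ``n_samples`` observations: ``ceil(sqrt(m))``."""
    return max(2, math.isqrt(n_samples - 1) + 1) if n_samples > 1 else 2


def discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency (quantile) binning, applied independently to each row.

    Each gene row is mapped to integer symbols ``0..bins-1`` so that the
    symbols split the samples into (near) equal-count groups.  Ties are broken
    by sample order (stable ranking); a constant row carries no information
    and maps to symbol 0 everywhere.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Continuous expression values, one row per gene.
    bins : int
        Number of bins per gene, ``2 <= bins <= n_samples``.

    Returns
    -------
    ndarray of int64, same shape as ``values``, entries in ``{0,..,bins-1}``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    n, m = values.shape
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if bins > m:
        raise ValueError(f"more bins than samples ({bins} > {m})")
    if not np.isfinite(values).all():
        raise ValueError("expression values must be finite (no NaN/inf)")

    symbols = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        row = values[i]
        if row.max() == row.min():
            symbols[i] = 0
            continue
        order = np.argsort(row, kind="stable")
        ranks = np.empty(m, dtype=np.int64)
        ranks[order] = np.arange(m)
        symbols[i] = (ranks * bins) // m
    return symbols


def _validate_vector(x) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("symbol vector must be one-dimensional")
    if x.size == 0:
        raise ValueError("symbol vector must be non-empty")
    return x.astype(np.int64, copy=False)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy(x) -> float:
    """Plug-in Shannon entropy of a symbol vector, in bits.

    ``H(X) = -sum_x p(x) log2 p(x)`` with the empirical ``p`` and the
    convention ``0 log 0 = 0``.
    """
    x = _validate_vector(x)
    offset = x.min()
    counts = np.bincount(x - offset)
    return _entropy_from_counts(counts)


def joint_code(vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Fold several symbol vectors into one vector coding their joint
    configuration, re-compacted so codes stay small."""
    code = None
    for v in vectors:
        v = _validate_vector(v)
        if code is None:
            code = np.unique(v, return_inverse=True)[1]
        else:
            if v.shape != code.shape:
                raise ValueError("symbol vectors must share a common length")
            base = int(v.max()) + 1
            code = np.unique(code * base + v, return_inverse=True)[1]
    if code is None:
        raise ValueError("need at least one vector")
    return code


def conditional_entropy(y, X: Sequence) -> float:
    """Plug-in conditional entropy ``H(Y | X1,..,Xk)`` in bits.

    Estimated over the *observed* joint configurations of the conditioning
    vectors (unobserved configurations carry zero empirical mass), via
    ``H(Y, X) - H(X)``.  With an empty conditioning set this is ``H(Y)``.
    Adding a conditioning vector can never increase the value.
    """
    y = _validate_vector(y)
    X = [_validate_vector(v) for v in X]
    for v in X:
        if v.shape != y.shape:
            raise ValueError("conditioning vectors must match the length of y")
    if not X:
        return entropy(y)
    x_code = joint_code(X)
    yx_code = joint_code([y, x_code])
    h_x = _entropy_from_counts(np.bincount(x_code))
    h_yx = _entropy_from_counts(np.bincount(yx_code))
    return max(0.0, h_yx - h_x)


def mutual_information(x, y) -> float:
    """Mutual information ``I(X,Y) = H(Y) - H(Y|X)`` in bits, clipped at 0."""
    x = _validate_vector(x)
    y = _validate_vector(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return max(0.0, entropy(y) - conditional_entropy(y, [x]))


def build_mim(symbols: np.ndarray) -> np.ndarray:
    """Pairwise mutual-information matrix of a discretized gene matrix.

    Parameters
    ----------
    symbols : ndarray of shape (n_genes, n_samples)
        Integer symbol matrix, one row per gene.

    Returns
    -------
    ndarray of shape (n_genes, n_genes)
        Symmetric non-negative matrix; entry (i, j) is I(g_i, g_j) and the
        diagonal holds each gene's entropy H(g_i).
    """
    symbols = np.asarray(symbols, dtype=np.int64)
    if symbols.ndim != 2:
        raise ValueError("expected a 2-D symbol matrix (genes x samples)")
    n = symbols.shape[0]
    ent = np.array([entropy(symbols[i]) for i in range(n)])
    mim = np.zeros((n, n))
    np.fill_diagonal(mim, ent)
    for i in range(n):
        for j in range(i + 1, n):
            joint = _entropy_from_counts(
                np.bincount(joint_code([symbols[i], symbols[j]]))
            )
            mi = max(0.0, ent[i] + ent[j] - joint)
            mim[i, j] = mim[j, i] = mi
    return mim
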