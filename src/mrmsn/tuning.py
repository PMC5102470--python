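"""Data-driven tuning of the relevance weight ``alpha`` and threshold ``T0``.

The relevance weight is read off the *local density* of the MI matrix: for a
cutoff distance ``d``, the density ``rho_c`` of gene c is the number of other
genes whose MI with c is at least ``d`` — a proxy for its in-degree.  The
cutoff comes from the most weakly connected gene (the one with the smallest
total MI): ``d`` is the largest MI in that gene's row, or, if that leaves
some gene with zero density, the mean of that row.  A network where most
genes have fewer than ``ceil(log2 n)`` dense neighbours is sparse, and
relevance is weighted up; a dense one weights significance up.

``T0`` is set to 70% of the largest MRMS score observed during an
unconstrained selection pass over all targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mrms import MRMSConfig, select_regulators

__all__ = ["DensityProfile", "local_density", "estimate_alpha", "estimate_t0"]


@dataclass
class DensityProfile:
    """Local-density summary of a mutual-information matrix.

    rho : per-gene count of neighbours with MI >= d.
    d : the cutoff distance actually used.
    gamma_gene : index of the gene minimizing the row-sum of MI.
    smg : per-gene row-sum of MI to all other genes.
    used_fallback_d : True when the mean-based cutoff had to replace the
        max-based one because some gene had zero density.
    """

    rho: np.ndarray
    d: float
    gamma_gene: int
    smg: np.ndarray
    used_fallback_d: bool


def local_density(mim: np.ndarray) -> DensityProfile:
    """Compute per-gene local densities from a mutual-information matrix."""
    mim = np.asarray(mim, dtype=float)
    n = mim.shape[0]
    if mim.ndim != 2 or mim.shape[1] != n:
        raise ValueError("mim must be a square matrix")
    if n < 2:
        raise ValueError("need at least 2 genes")

    off = mim.copy()
    np.fill_diagonal(off, 0.0)
    smg = off.sum(axis=1)
    gamma = int(np.argmin(smg))  # ties -> smallest index via argmin

    gamma_row = off[gamma].copy()
    gamma_row[gamma] = -np.inf
    d = float(np.max(gamma_row))

    def _rho(cutoff: float) -> np.ndarray:
        counts = np.empty(n, dtype=np.int64)
        for c in range(n):
            row = np.delete(off[c], c)
            counts[c] = int(np.count_nonzero(row >= cutoff))
        return counts

    rho = _rho(d)
    used_fallback = False
    if np.any(rho == 0):
        d = float(np.delete(off[gamma], gamma).mean())
        rho = _rho(d)
        used_fallback = True
    return DensityProfile(
        rho=rho, d=d, gamma_gene=gamma, smg=smg, used_fallback_d=used_fallback
    )


def estimate_alpha(profile: DensityProfile, n: int) -> float:
    """Relevance weight from density: fraction of genes whose density falls
    short of ``ceil(log2 n)``, clamped into [0.1, 0.9]."""
    k = math.ceil(math.log2(n))
    raw = float(np.count_nonzero(k - profile.rho > 0)) / n
    return min(0.9, max(0.1, raw))


def estimate_t0(
    mim: np.ndarray,
    symbols: np.ndarray,
    alpha: float,
    k: int,
    admissible: np.ndarray | None = None,
    fraction: float = 0.7,
) -> float:
    """Score threshold: 70% of the maximum MRMS score over an unconstrained
    selection pass (``T0 = -inf``) for every target gene.

    Only scores of accepted picks are collected — the scores actually
    observed while regulators are being selected.
    """
    n = mim.shape[0]
    config = MRMSConfig(alpha=alpha, k=k, t0=-np.inf)
    best = -np.inf
    seen = False
    for target in range(n):
        mask = None if admissible is None else admissible[target]
        sel = select_regulators(target, mim, symbols, config, mask)
        for s in sel.scores:
            seen = True
            if s > best:
                best = s
    if not seen:
        raise ValueError("no scores collected; cannot estimate T0")
    return fraction * best
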