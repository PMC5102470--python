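"""Maximum-relevance / maximum-significance (MRMS) regulator selection.

For one target gene the method greedily grows a set ``V`` of regulator
genes.  A candidate ``g_m`` is scored by

    score = alpha * I(g_m, g_c) + (1 - alpha) * [H(g_c | V) - H(g_c | V + g_m)]

i.e. a convex combination of its *relevance* (mutual information with the
target) and its *significance* (the drop in the target's conditional entropy
when the candidate joins the already-selected set).  The first regulator is
the maximum-relevance candidate; subsequent candidates are accepted while the
best score stays at or above the threshold ``T0`` and ``|V| < K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .infotheory import _entropy_from_counts, conditional_entropy, joint_code

__all__ = [
    "MRMSConfig",
    "RegulatorSelection",
    "relevance",
    "significance",
    "mrms_score",
    "select_regulators",
    "default_k",
]


def default_k(n_genes: int) -> int:
    """Regulator budget per target: ``ceil(log2 n)``, reflecting sparsity."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    return max(1, math.ceil(math.log2(n_genes)))


@dataclass
class MRMSConfig:
    """Parameters of the MRMS selection.

    alpha : relevance weight in [0.1, 0.9].
    k : maximum number of regulators per target (default ``ceil(log2 n)``).
    t0 : score threshold; candidates after the first are accepted only while
        the best score is >= t0.  May be ``-inf`` for an unconstrained pass.
    epsilon : per-gene MIM threshold factor in (0, 1).
    """

    alpha: float
    k: int
    t0: float
    epsilon: float = 0.01

    def __post_init__(self):
        if not 0.1 <= self.alpha <= 0.9:
            raise ValueError("alpha must lie in [0.1, 0.9]")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")


@dataclass
class RegulatorSelection:
    """Ordered regulator picks for one target gene.

    ``scores[i]`` is the MRMS objective value of ``regulators[i]`` at the
    moment it was selected; ``first_regulator`` is the initial
    maximum-relevance pick (None when no candidate was admissible).
    """

    target: int
    regulators: list = field(default_factory=list)
    scores: list = field(default_factory=list)
    first_regulator: Optional[int] = None


def relevance(target: int, candidate: int, mim: np.ndarray) -> float:
    """Relevance of a candidate regulator: its MI with the target."""
    if target == candidate:
        raise ValueError("a gene cannot be its own candidate regulator")
    return float(mim[candidate, target])


def significance(
    candidate: int, target: int, V: Sequence[int], symbols: np.ndarray
) -> float:
    """Entropy reduction ``H(g_c|V) - H(g_c|V + g_m)`` of adding a candidate.

    Non-negative by the monotonicity of conditional entropy.  With ``V``
    empty it reduces to the mutual information I(g_m, g_c).
    """
    if candidate in V:
        raise ValueError("candidate already selected")
    if candidate == target:
        raise ValueError("a gene cannot be its own candidate regulator")
    y = symbols[target]
    cond = [symbols[v] for v in V]
    h_v = conditional_entropy(y, cond)
    h_vm = conditional_entropy(y, cond + [symbols[candidate]])
    return max(0.0, h_v - h_vm)


def mrms_score(
    candidate: int,
    target: int,
    V: Sequence[int],
    alpha: float,
    mim: np.ndarray,
    symbols: np.ndarray,
) -> float:
    """The MRMS objective: ``alpha * relevance + (1 - alpha) * significance``."""
    return alpha * relevance(target, candidate, mim) + (1.0 - alpha) * significance(
        candidate, target, V, symbols
    )


def select_regulators(
    target: int,
    mim: np.ndarray,
    symbols: np.ndarray,
    config: MRMSConfig,
    admissible: Optional[np.ndarray] = None,
) -> RegulatorSelection:
    """First-order incremental search for the regulators of one target.

    The candidate set starts from ``admissible`` (a boolean mask over genes;
    the target itself is always excluded).  The maximum-relevance candidate is
    taken first, unconditionally; each later round picks the argmax of the
    MRMS objective among the remaining candidates and stops when that best
    score falls below ``config.t0`` or ``K`` regulators have been selected.
    Ties are broken toward the smallest gene index for determinism.

    With no admissible candidate the selection is returned empty
    (``first_regulator`` is None); the pipeline applies its fallback.
    """
    n = mim.shape[0]
    if admissible is None:
        mask = np.ones(n, dtype=bool)
    else:
        mask = np.asarray(admissible, dtype=bool).copy()
    mask[target] = False

    sel = RegulatorSelection(target=target)
    candidates = np.flatnonzero(mask)
    if candidates.size == 0:
        return sel

    # Step 2-3: maximum-relevance first pick, exempt from the T0 test.  Its
    # recorded score is the MRMS objective with V empty, which equals its
    # relevance (significance collapses to the same MI).
    rel = mim[candidates, target]
    first = int(candidates[int(np.argmax(rel))])
    sel.regulators.append(first)
    sel.scores.append(float(mim[first, target]))
    sel.first_regulator = first
    mask[first] = False

    # Step 4-5: greedy rounds under the score threshold and the K budget.
    # Joint configurations are folded into compact integer codes so each
    # candidate evaluation is a pair of bincount entropies, not a fresh
    # multi-column unique().
    compact = np.empty_like(symbols)
    bases = np.empty(symbols.shape[0], dtype=np.int64)
    for g in range(symbols.shape[0]):
        _, compact[g] = np.unique(symbols[g], return_inverse=True)
        bases[g] = compact[g].max() + 1
    y = compact[target]
    y_base = bases[target]
    v_code = joint_code([compact[first]])
    while len(sel.regulators) < config.k:
        candidates = np.flatnonzero(mask)
        if candidates.size == 0:
            break
        h_v = _entropy_from_counts(
            np.bincount(v_code * y_base + y)
        ) - _entropy_from_counts(np.bincount(v_code))
        best_idx, best_score = -1, -np.inf
        for c in candidates:
            x_code = v_code * bases[c] + compact[c]
            h_x = _entropy_from_counts(np.bincount(x_code))
            h_yx = _entropy_from_counts(np.bincount(x_code * y_base + y))
            sig = max(0.0, h_v - max(0.0, h_yx - h_x))
            score = config.alpha * mim[c, target] + (1.0 - config.alpha) * sig
            # scores within 1e-12 count as tied; the earlier (smaller) gene
            # index wins, keeping the trace stable under fp noise
            if score > best_score + 1e-12:
                best_idx, best_score = int(c), score
        if best_score < config.t0:
            break
        sel.regulators.append(best_idx)
        sel.scores.append(float(best_score))
        mask[best_idx] = False
        v_code = joint_code([v_code, compact[best_idx]])
    return sel
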