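"""Scikit-learn style estimator for MRMS network inference.

`MRMSNetworkInference` is an unsupervised structure estimator: ``fit`` takes
an expression matrix of shape (n_samples, n_genes) — genes are features, as
in any sklearn estimator — and recovers an undirected gene regulatory
network in three stages:

1. build the pairwise mutual-information matrix (MIM) on quantile-discretized
   data and zero, per target gene, every entry below ``theta_i = epsilon *
   max(M_i)``;
2. for every gene as target, greedily select up to K regulators maximizing
   ``alpha * relevance + (1 - alpha) * significance`` above a threshold T0;
3. keep an undirected edge i-j only when i selected j AND j selected i
   (mutual constraint), then reconnect any isolated gene to its
   first-selected regulator so every gene keeps at least one edge.

``alpha`` and ``t0`` default to "auto" and are tuned from the data (local
density for alpha, 70% of the maximum observed score for T0).
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .infotheory import build_mim, default_bins, discretize
from .mrms import MRMSConfig, default_k, select_regulators

__all__ = ["MRMSNetworkInference", "threshold_mim", "assemble_network"]


def assemble_network(
    selections, mim: np.ndarray, n: Optional[int] = None
) -> set[tuple[int, int]]:
    """Stage-3 assembly: mutual constraint plus the isolation fallback.

    An undirected edge (i, j) is kept iff i selected j AND j selected i.
    Every gene left without an incident edge then contributes the edge to its
    first-selected regulator (or, lacking any selection, to its argmax-MI
    partner), so each gene ends with degree >= 1.  Isolation is judged on the
    constraint outcome alone, making the fallback order-independent.
    """
    if n is None:
        n = mim.shape[0]
    regsets = [set(s.regulators) for s in selections]
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in regsets[i]:
            if i in regsets[j]:
                edges.add((min(i, j), max(i, j)))
    touched = {g for e in edges for g in e}
    for i in range(n):
        if i in touched:
            continue
        partner = selections[i].first_regulator
        if partner is None:
            row = np.asarray(mim[i], dtype=float).copy()
            row[i] = -np.inf
            partner = int(np.argmax(row))
        edges.add((min(i, partner), max(i, partner)))
    return edges


def threshold_mim(mim: np.ndarray, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene thresholding of a MIM.

    For each target gene i the threshold is ``theta_i = epsilon * max_{j != i}
    M[i, j]``; entries below it are zeroed and the candidate is marked
    inadmissible *for that target*.  Because theta is per row, admissibility
    is directional: j may remain a candidate for i while i is dropped for j.

    Returns
    -------
    (adjusted, admissible)
        ``adjusted`` is the zeroed copy (diagonal untouched); ``admissible``
        is a boolean matrix where ``admissible[i, j]`` says gene j may be a
        candidate regulator of target i (diagonal False).
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    mim = np.asarray(mim, dtype=float)
    n = mim.shape[0]
    off = mim.copy()
    np.fill_diagonal(off, -np.inf)
    theta = epsilon * off.max(axis=1)

    admissible = off >= theta[:, None]
    np.fill_diagonal(admissible, False)
    adjusted = mim.copy()
    drop = ~admissible
    np.fill_diagonal(drop, False)
    adjusted[drop] = 0.0
    return adjusted, admissible


class MRMSNetworkInference(BaseEstimator):
    """Infer an undirected gene regulatory network from expression data.

    Parameters
    ----------
    alpha : float in [0.1, 0.9] or "auto"
        Weight of relevance against significance in the selection objective.
        "auto" estimates it from the local density of the MI matrix.
    t0 : float or "auto"
        Score threshold for accepting regulators after the first; "auto"
        sets it to 70% of the maximum score seen in an unconstrained pass.
    k : int or "auto"
        Regulator budget per target gene; "auto" resolves to ``ceil(log2 n)``.
    epsilon : float in (0, 1), default 0.01
        Factor of each gene's row maximum used to zero weak MI entries.
    bins : int or "auto"
        Bins for per-gene quantile discretization; "auto" is ``ceil(sqrt(m))``.

    Attributes
    ----------
    gene_ids_ : list of gene labels (DataFrame columns, else "G1".."Gn").
    mim_ : (n, n) mutual-information matrix, diagonal = per-gene entropy.
    admissible_ : (n, n) boolean directional candidate mask after stage 1.
    alpha_, t0_, k_, bins_ : resolved parameter values.
    selections_ : list of per-target RegulatorSelection, in gene order.
    network_ : networkx.Graph, the inferred undirected network.

    Examples
    --------
    >>> from mrmsn.synthetic import SimulationSpec, simulate
    >>> gold, expr = simulate(SimulationSpec(n=10, m=200, seed=0))
    >>> model = MRMSNetworkInference().fit(expr.T)
    >>> sorted(model.network_.edges)  # doctest: +SKIP
    """

    def __init__(self, alpha="auto", t0="auto", k="auto", epsilon=0.01, bins="auto"):
        self.alpha = alpha
        self.t0 = t0
        self.k = k
        self.epsilon = epsilon
        self.bins = bins

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit the network on expression data of shape (n_samples, n_genes)."""
        gene_ids = None
        if isinstance(X, pd.DataFrame):
            gene_ids = [str(c) for c in X.columns]
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_genes)")
        m, n = X.shape
        if n < 2:
            raise ValueError("need at least 2 genes")
        if m < 2:
            raise ValueError("need at least 2 samples")
        if not np.isfinite(X).all():
            raise ValueError("X contains missing or non-finite values")
        if gene_ids is None:
            gene_ids = [f"G{i + 1}" for i in range(n)]
        if len(set(gene_ids)) != n:
            raise ValueError("gene identifiers must be unique")

        self.n_features_in_ = n
        self.n_samples_ = m
        self.gene_ids_ = gene_ids

        self.bins_ = default_bins(m) if self.bins == "auto" else int(self.bins)
        self.k_ = default_k(n) if self.k == "auto" else int(self.k)

        # Stage 1: MIM on discretized data, per-gene thresholding.
        self.symbols_ = discretize(X.T, self.bins_)
        self.mim_ = build_mim(self.symbols_)
        self.thresholded_mim_, self.admissible_ = threshold_mim(
            self.mim_, self.epsilon
        )

        if self.alpha == "auto":
            from .tuning import estimate_alpha, local_density

            self.density_ = local_density(self.mim_)
            self.alpha_ = estimate_alpha(self.density_, n)
        else:
            self.alpha_ = float(self.alpha)

        if self.t0 == "auto":
            from .tuning import estimate_t0

            self.t0_ = estimate_t0(
                self.mim_, self.symbols_, self.alpha_, self.k_, self.admissible_
            )
        else:
            self.t0_ = float(self.t0)

        # Stage 2: per-target regulator selection.
        config = MRMSConfig(
            alpha=self.alpha_, k=self.k_, t0=self.t0_, epsilon=self.epsilon
        )
        self.selections_ = [
            select_regulators(t, self.mim_, self.symbols_, config, self.admissible_[t])
            for t in range(n)
        ]

        # Stage 3: mutual constraint, then the at-least-one-edge fallback.
        edges = assemble_network(self.selections_, self.mim_, n)

        g = nx.Graph()
        g.add_nodes_from(gene_ids)
        g.add_edges_from((gene_ids[i], gene_ids[j]) for i, j in edges)
        self.network_ = g
        self._edge_scores = None
        return self

    # ------------------------------------------------------------------
    def score_edges(self) -> dict[tuple[str, str], float]:
        """Score every unordered gene pair by the MRMS objective.

        Runs the greedy selection untruncated (``T0 = -inf``, ``K = n - 1``)
        for every target and assigns each pair the larger of the two
        directional acceptance scores; pairs never scored get 0.  Useful for
        ROC sweeps over a range of thresholds.  Cached after the first call.
        """
        self._check_fitted()
        if self._edge_scores is not None:
            return self._edge_scores
        n = self.n_features_in_
        config = MRMSConfig(
            alpha=self.alpha_, k=max(1, n - 1), t0=-np.inf, epsilon=self.epsilon
        )
        best = np.zeros((n, n))
        for t in range(n):
            sel = select_regulators(
                t, self.mim_, self.symbols_, config, self.admissible_[t]
            )
            for g, s in zip(sel.regulators, sel.scores):
                if s > best[t, g]:
                    best[t, g] = s
        sym = np.maximum(best, best.T)
        ids = self.gene_ids_
        self._edge_scores = {
            (ids[i], ids[j]): float(sym[i, j]) for i, j in combinations(range(n), 2)
        }
        return self._edge_scores

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit(X) first")

    @property
    def edges_(self) -> set[tuple[str, str]]:
        """Inferred undirected edges as sorted gene-id pairs."""
        self._check_fitted()
        return {tuple(sorted(e)) for e in self.network_.edges}
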