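"""Three-stage network inference pipeline (functional front end).

These are thin wrappers over :class:`mrmsn.estimator.MRMSNetworkInference`
for callers that hold a genes-by-samples expression table (the usual
orientation of expression files) rather than an sklearn-style
samples-by-features matrix.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .estimator import MRMSNetworkInference, threshold_mim
from .mrms import MRMSConfig

__all__ = ["threshold_mim", "infer_network", "edge_scores", "fit_pipeline"]


def _to_samples_by_genes(data, gene_ids=None):
    if isinstance(data, pd.DataFrame):
        return data.T
    arr = np.asarray(data, dtype=float)
    if gene_ids is None:
        gene_ids = [f"G{i + 1}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr.T, columns=list(gene_ids))


def fit_pipeline(
    data,
    config: Optional[MRMSConfig] = None,
    gene_ids=None,
    bins="auto",
) -> MRMSNetworkInference:
    """Fit the full pipeline on a genes-by-samples table and return the
    fitted estimator.  ``config=None`` auto-tunes alpha, T0 and K."""
    if config is None:
        est = MRMSNetworkInference(bins=bins)
    else:
        est = MRMSNetworkInference(
            alpha=config.alpha, t0=config.t0, k=config.k,
            epsilon=config.epsilon, bins=bins,
        )
    return est.fit(_to_samples_by_genes(data, gene_ids))


def infer_network(
    data, config: Optional[MRMSConfig] = None, gene_ids=None, bins="auto"
) -> nx.Graph:
    """Infer the undirected gene network from a genes-by-samples table."""
    return fit_pipeline(data, config, gene_ids, bins).network_


def edge_scores(
    data, config: Optional[MRMSConfig] = None, gene_ids=None, bins="auto"
) -> dict:
    """MRMS scores for every unordered gene pair (for ROC threshold sweeps)."""
    return fit_pipeline(data, config, gene_ids, bins).score_edges()
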