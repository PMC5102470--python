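"""Synthetic gold-standard networks with matching expression data.

Generates small sparse networks (linear chains, random sparse DAGs, hubs)
together with continuous expression matrices in which each regulated gene is
a noisy nonlinear (tanh) function of its regulators.  The nonlinearity
deliberately exercises the information-theoretic estimators — linear
Gaussian coupling would also create dependence but would understate why MI
is used at all.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SimulationSpec", "simulate"]

TOPOLOGIES = ("chain", "random-sparse", "hub")


@dataclass
class SimulationSpec:
    """Conditions of one simulated dataset.

    n, m : gene and sample counts (the benchmark datasets this emulates run
        4-50 genes and 9-125 samples).
    topology : "chain" (g1 -> g2 -> ... -> gn), "random-sparse" (a random DAG
        with ``edges`` edges) or "hub" (g1 regulates everyone).
    edges : edge count for random-sparse; defaults to n.  Chains force n-1,
        hubs n-1.
    coupling : regulator-to-target signal strength in (0, 1].
    noise_sd : standard deviation of the additive Gaussian noise.
    seed : RNG seed; identical specs give identical outputs.
    """

    n: int
    m: int
    topology: str = "chain"
    edges: int | None = None
    coupling: float = 0.95
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.m < 2:
            raise ValueError("need n >= 2 genes and m >= 2 samples")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        max_edges = self.n * (self.n - 1) // 2
        if self.edges is not None and not 1 <= self.edges <= max_edges:
            raise ValueError(f"edge count must lie in [1, {max_edges}]")


def _directed_edges(spec: SimulationSpec, rng: np.random.Generator):
    n = spec.n
    if spec.topology == "chain":
        return [(i, i + 1) for i in range(n - 1)]
    if spec.topology == "hub":
        return [(0, j) for j in range(1, n)]
    # random-sparse: sample unordered pairs, orient low -> high index (a DAG)
    want = spec.edges if spec.edges is not None else n
    all_pairs = list(combinations(range(n), 2))
    if want > len(all_pairs):
        raise ValueError("edge count exceeds the number of gene pairs")
    idx = rng.choice(len(all_pairs), size=want, replace=False)
    return [all_pairs[i] for i in sorted(idx)]


def simulate(spec: SimulationSpec) -> tuple[nx.Graph, pd.DataFrame]:
    """Draw a gold network and a matching expression matrix.

    Root genes (no regulators) are independent standard normals; every other
    gene is ``coupling * tanh(sum of its regulators) + N(0, noise_sd^2)``,
    evaluated in topological order, so parent-child MI dominates MI between
    non-adjacent genes whenever coupling is strong relative to the noise.

    Returns
    -------
    (gold, expression)
        ``gold`` is the undirected true network over "G1".."Gn";
        ``expression`` is a genes-by-samples DataFrame (rows "G1".."Gn",
        columns "S1".."Sm").
    """
    rng = np.random.default_rng(spec.seed)
    directed = _directed_edges(spec, rng)
    n, m = spec.n, spec.m

    parents: list[list[int]] = [[] for _ in range(n)]
    for a, b in directed:
        parents[b].append(a)

    values = np.empty((n, m))
    for g in range(n):  # indices are already a topological order
        noise = rng.normal(0.0, 1.0 if not parents[g] else spec.noise_sd, size=m)
        if parents[g]:
            drive = np.tanh(values[parents[g]].sum(axis=0))
            values[g] = spec.coupling * drive + noise
        else:
            values[g] = noise

    ids = [f"G{i + 1}" for i in range(n)]
    gold = nx.Graph()
    gold.add_nodes_from(ids)
    gold.add_edges_from((ids[a], ids[b]) for a, b in directed)
    expr = pd.DataFrame(values, index=ids, columns=[f"S{j + 1}" for j in range(m)])
    return gold, expr
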