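"""Readers and writers for expression tables and network edge lists."""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
]


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_expression(path, genes_in_rows: bool = True) -> pd.DataFrame:
    """Read a delimited expression table into a genes-by-samples DataFrame.

    The delimiter (tab or comma) and the presence of a header row are
    autodetected; the first column holds gene identifiers.  Benchmark files
    that store samples in rows can be transposed with
    ``genes_in_rows=False``.
    """
    text = Path(path).read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    tokens = first.replace(",", "\t").split("\t" if sep != r"\s+" else None)
    has_header = len(tokens) > 1 and not all(_is_number(t) for t in tokens[1:])

    df = pd.read_csv(
        _io.StringIO(text),
        sep=sep,
        header=0 if has_header else None,
        index_col=0,
        engine="python",
    )
    df.index = df.index.map(str)
    df = df.astype(float)
    if not genes_in_rows:
        df = df.T
    if df.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression file")
    if df.isna().any().any():
        raise ValueError("expression file contains missing values")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    """Write a genes-by-samples DataFrame as a tab-delimited table."""
    df.to_csv(path, sep="\t", index_label="gene")


def read_network(path, nodes: Optional[Iterable[str]] = None) -> nx.Graph:
    """Read an undirected network from an edge list.

    Accepts plain two-column lines ("G1 G2"), SIF lines ("G1 pp G2") and
    DREAM-style signed lines ("G1 G2 1"); lines whose trailing label is 0
    mark non-edges and are skipped.  Direction is collapsed to unordered
    pairs.  ``nodes``, when given, fixes the gene universe so isolated genes
    are kept.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(str(x) for x in nodes)
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if len(parts) == 2:
            a, b = parts
        elif len(parts) == 3:
            a, mid, b = parts
            if _is_number(b):  # DREAM style: "G1 G2 1" / "G1 G2 0"
                a, b, flag = parts
                if float(flag) == 0:
                    g.add_nodes_from((a, b))
                    continue
            else:  # SIF style: "G1 pp G2"
                pass
        else:
            raise ValueError(f"cannot parse edge-list line: {line!r}")
        if a != b:
            g.add_edge(a, b)
        else:
            g.add_node(a)
    return g


def write_network(g: nx.Graph, path, fmt: str = "edgelist") -> None:
    """Write a network as ``edgelist`` ("A B"), ``sif`` ("A pp B") or a
    symmetric 0/1 ``adjacency`` matrix with labelled rows and columns."""
    path = Path(path)
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    if fmt == "edgelist":
        path.write_text("".join(f"{a}\t{b}\n" for a, b in edges))
    elif fmt == "sif":
        path.write_text("".join(f"{a}\tpp\t{b}\n" for a, b in edges))
    elif fmt == "adjacency":
        ids = sorted(g.nodes)
        index = {x: i for i, x in enumerate(ids)}
        adj = np.zeros((len(ids), len(ids)), dtype=int)
        for a, b in edges:
            adj[index[a], index[b]] = adj[index[b], index[a]] = 1
        pd.DataFrame(adj, index=ids, columns=ids).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown network format: {fmt!r}")
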