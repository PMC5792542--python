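"""Reading and writing networks, traits and groups as plain CSV / GraphML.

Edge lists are undirected: one row per dyad with positive weight,
columns ``node_i,node_j,weight``, 0-based integer node ids.  Trait
tables have columns ``node_id,trait``.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .quantgen import Group

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_trait_table",
    "read_trait_table",
    "write_group_csv",
    "write_graphml",
]


def write_edge_list(w: np.ndarray, path) -> None:
    """Write the upper triangle of a weight matrix as an undirected edge list."""
    w = np.asarray(w, dtype=float)
    i, j = np.triu_indices(w.shape[0], k=1)
    keep = w[i, j] > 0
    pd.DataFrame(
        {"node_i": i[keep], "node_j": j[keep], "weight": w[i, j][keep]}
    ).to_csv(path, index=False)


def read_edge_list(path, n: int | None = None) -> np.ndarray:
    """Read an undirected edge list into a symmetric weight matrix.

    ``n`` may be given when isolated high-index nodes exist; otherwise
    the node count is inferred as ``max id + 1``.
    """
    df = pd.read_csv(path)
    required = {"node_i", "node_j", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    if len(df) == 0 and n is None:
        raise ValueError("cannot infer node count from an empty edge list")
    inferred = int(max(df["node_i"].max(), df["node_j"].max())) + 1 if len(df) else 0
    n = inferred if n is None else int(n)
    if n < inferred:
        raise ValueError(f"n={n} smaller than largest node id {inferred - 1}")
    w = np.zeros((n, n))
    ii = df["node_i"].to_numpy(dtype=int)
    jj = df["node_j"].to_numpy(dtype=int)
    ww = df["weight"].to_numpy(dtype=float)
    w[ii, jj] = ww
    w[jj, ii] = ww
    np.fill_diagonal(w, 0.0)
    return w


def write_trait_table(traits, path) -> None:
    traits = np.asarray(traits, dtype=float)
    pd.DataFrame({"node_id": np.arange(traits.shape[0]), "trait": traits}).to_csv(
        path, index=False
    )


def read_trait_table(path) -> np.ndarray:
    """Read a ``node_id,trait`` table into an array ordered by node id."""
    df = pd.read_csv(path)
    if not {"node_id", "trait"}.issubset(df.columns):
        raise ValueError("trait table must have columns node_id,trait")
    df = df.sort_values("node_id")
    ids = df["node_id"].to_numpy(dtype=int)
    if not np.array_equal(ids, np.arange(len(ids))):
        raise ValueError("node ids must be contiguous 0-based integers")
    return df["trait"].to_numpy(dtype=float)


def write_group_csv(group: Group, path) -> None:
    """Write one group's per-individual values: ``node_id,x,y,a,e,eta,z,t``."""
    n = group.n
    pd.DataFrame(
        {
            "node_id": np.arange(n),
            "x": group.points[:, 0],
            "y": group.points[:, 1],
            "a": group.genetics.a,
            "e": group.genetics.e,
            "eta": group.eta,
            "z": group.z,
            "t": group.t,
        }
    ).to_csv(path, index=False)


def write_graphml(w: np.ndarray, path, traits=None) -> None:
    """Export a realized network for visualization in standard tools."""
    w = np.asarray(w, dtype=float)
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    if traits is not None:
        traits = np.asarray(traits, dtype=float)
        nx.set_node_attributes(g, {i: float(t) for i, t in enumerate(traits)}, "trait")
    i, j = np.triu_indices(w.shape[0], k=1)
    keep = w[i, j] > 0
    g.add_weighted_edges_from(
        zip(i[keep].tolist(), j[keep].tolist(), w[i, j][keep].tolist())
    )
    nx.write_graphml(g, Path(path))
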