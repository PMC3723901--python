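"""Directed-graph container shared by the generators, measures and simulators.

The network is a plain binary adjacency matrix: entry ``(i, j)`` is 1 when
there is a synapse *from* neuron ``i`` *to* neuron ``j``.  Self-connections
are excluded throughout.  Spatially embedded generators attach per-node
coordinates, and excitatory/inhibitory population labels are attached after
generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx

__all__ = ["DirectedGraph", "read_edge_list", "write_edge_list"]

EXCITATORY = 0
INHIBITORY = 1


@dataclass
class DirectedGraph:
    """Binary directed graph on ``n_nodes`` neurons.

    Parameters
    ----------
    adjacency
        Boolean ``(n, n)`` matrix, ``adjacency[i, j]`` meaning an edge
        from node ``i`` to node ``j``.  The diagonal must be zero.
    positions
        Optional ``(n, d)`` embedding coordinates (ring: d=2, torus: d=4).
    labels
        Optional per-node population labels (0 = excitatory, 1 = inhibitory).
    """

    adjacency: np.ndarray
    positions: np.ndarray | None = None
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        a = a.astype(bool)
        if a.diagonal().any():
            raise ValueError("self-connections are excluded")
        self.adjacency = a

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edge_array(self) -> np.ndarray:
        """``(m, 2)`` array of (pre, post) node ids."""
        pre, post = np.nonzero(self.adjacency)
        return np.column_stack([pre, post])

    # -- populations ------------------------------------------------------
    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def excitatory_ids(self) -> np.ndarray:
        if self.labels is None:
            return np.arange(self.n_nodes)
        return np.flatnonzero(self.labels == EXCITATORY)

    def inhibitory_ids(self) -> np.ndarray:
        if self.labels is None:
            return np.array([], dtype=np.int64)
        return np.flatnonzero(self.labels == INHIBITORY)

    # -- conversions ------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.from_numpy_array(self.adjacency.astype(np.int8), create_using=nx.DiGraph)
        if self.labels is not None:
            nx.set_node_attributes(
                g,
                {i: ("inhibitory" if v else "excitatory") for i, v in enumerate(self.labels)},
                "population",
            )
        if self.positions is not None:
            nx.set_node_attributes(
                g, {i: ",".join(map(repr, p)) for i, p in enumerate(self.positions)}, "position"
            )
        return g

    def to_igraph(self):
        import igraph as ig

        return ig.Graph(
            n=self.n_nodes, edges=[tuple(e) for e in self.edge_array()], directed=True
        )

    # -- I/O ---------------------------------------------------------------
    def write_edge_list(self, path: str | Path) -> None:
        write_edge_list(self, path)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def write_edge_list(graph: DirectedGraph, path: str | Path) -> None:
    """Write a headered edge-list: one ``pre post`` pair per line, 0-based."""
    path = Path(path)
    lines = [f"# n_nodes {graph.n_nodes}"]
    if graph.labels is not None:
        inh = " ".join(map(str, graph.inhibitory_ids()))
        lines.append(f"# inhibitory {inh}")
    lines += [f"{i} {j}" for i, j in graph.edge_array()]
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> DirectedGraph:
    """Read the edge-list format written by :func:`write_edge_list`.

    Headerless files are accepted: ``n_nodes`` then defaults to
    ``max(node id) + 1``.
    """
    n_nodes = None
    inhibitory: list[int] = []
    edges: list[tuple[int, int]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts and parts[0] == "n_nodes":
                n_nodes = int(parts[1])
            elif parts and parts[0] == "inhibitory":
                inhibitory = [int(x) for x in parts[1:]]
            continue
        i, j = line.split()[:2]
        edges.append((int(i), int(j)))
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=-1)
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for i, j in edges:
        adj[i, j] = True
    labels = None
    if inhibitory:
        labels = np.zeros(n_nodes, dtype=np.int8)
        labels[inhibitory] = INHIBITORY
    return DirectedGraph(adj, labels=labels)
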