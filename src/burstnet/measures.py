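"""Graph-theoretic measures of directed networks.

The full structural feature vector has 21 entries: clustering coefficient
(CC), harmonic path length (PL), node-betweenness (NB), out-degree
deviation (OD), degree correlation (DC), length-to-self (LtS), maximum
eigenvalue of the adjacency (MEig), the 13 connected three-node motif
counts (Mot1-Mot13), and the realized average in-degree.

Motif numbering
---------------
The 13 weakly-connected isomorphism classes of directed 3-node subgraphs
are ordered by edge count; within the 3-edge group the feed-forward loop
is Mot5.  In standard triad-census nomenclature::

    Mot1  021D   a <- b -> c           Mot8  201   a <-> b <-> c
    Mot2  021U   a -> b <- c           Mot9  120D  b -> a <- c, b <-> c
    Mot3  021C   a -> b -> c           Mot10 120U  b <- a -> c, b <-> c
    Mot4  111D   a <-> b <- c          Mot11 120C  a -> b -> c, a <-> c
    Mot5  030T   a -> b -> c, a -> c   Mot12 210   five edges
    Mot6  111U   a <-> b -> c          Mot13 300   all six edges
    Mot7  030C   a -> b -> c -> a

    (Mot9 120D: a -> b, a -> c, b <-> c; Mot10 120U: b -> a, c -> a, b <-> c.)

A triple is classified by its full induced subgraph, so each connected
unordered triple contributes to exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import networkx as nx
from numba import njit

from .graph import DirectedGraph

__all__ = [
    "GraphMeasures",
    "MOTIF_ORDER",
    "MEASURE_NAMES",
    "clustering_coefficient",
    "local_clustering",
    "harmonic_path_length",
    "node_betweenness",
    "out_degree_deviation",
    "degree_correlation",
    "length_to_self",
    "max_eigenvalue",
    "motif_counts",
    "compute_measures",
]

MOTIF_ORDER = (
    "021D", "021U", "021C", "111D", "030T", "111U", "030C",
    "201", "120D", "120U", "120C", "210", "300",
)

MEASURE_NAMES = (
    ("CC", "PL", "NB", "OD", "DC", "LtS", "MEig")
    + tuple(f"Mot{i}" for i in range(1, 14))
    + ("Degree",)
)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------
def local_clustering(graph: DirectedGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-node directed clustering coefficients (Fagiolo convention).

    A triangle requires at least a unidirected edge between each of the
    three node pairs, and edge directions are respected: making an edge
    bidirectional doubles the number of counted triangles.  The node's
    coefficient normalizes the directed-triangle count by the number
    attainable were its neighborhood fully bidirectionally connected.

    Returns ``(cc, eligible)`` where ``eligible`` marks nodes with more
    than one neighbor (only those enter the network average).
    """
    a = graph.adjacency.astype(np.float64)
    sym = a + a.T
    tri = np.einsum("ij,jk,ki->i", sym, sym, sym) / 2.0
    d_tot = a.sum(axis=0) + a.sum(axis=1)
    d_bi = (graph.adjacency & graph.adjacency.T).sum(axis=1)
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    n_neighbors = (graph.adjacency | graph.adjacency.T).sum(axis=1)
    eligible = n_neighbors > 1
    cc = np.zeros(graph.n_nodes)
    np.divide(tri, denom, out=cc, where=denom > 0)
    return cc, eligible


def clustering_coefficient(graph: DirectedGraph) -> float:
    """Network CC: mean local clustering over nodes with > 1 neighbor."""
    cc, eligible = local_clustering(graph)
    if not eligible.any():
        return 0.0
    return float(cc[eligible].mean())


# ---------------------------------------------------------------------------
# path-based measures (igraph BFS backend)
# ---------------------------------------------------------------------------
def _distance_matrix(graph: DirectedGraph) -> np.ndarray:
    d = np.asarray(graph.to_igraph().distances(mode="out"), dtype=float)
    return d


def harmonic_path_length(graph: DirectedGraph) -> float:
    """Harmonic mean of pairwise geodesic distances.

    Unreachable pairs sit at infinite distance and contribute zero
    reciprocal; a graph in which no ordered pair is reachable has
    infinite path length (returned as ``inf``).
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("harmonic path length needs at least two nodes")
    d = _distance_matrix(graph)
    np.fill_diagonal(d, np.inf)
    recip = np.zeros_like(d)
    np.divide(1.0, d, out=recip, where=np.isfinite(d))
    total = recip.sum()
    if total == 0:
        return np.inf
    return float(n * (n - 1) / total)


def node_betweenness(graph: DirectedGraph) -> float:
    """Mean over nodes of the shortest-path betweenness.

    A node on ``g`` of the ``G`` equally short geodesics between an
    ordered pair (s, t), s != t != node, earns the fraction ``g / G``.
    """
    if graph.n_nodes < 3:
        raise ValueError("node-betweenness needs at least three nodes")
    b = graph.to_igraph().betweenness(directed=True)
    return float(np.mean(b))


def length_to_self(graph: DirectedGraph) -> float:
    """Harmonic mean of per-node shortest feedback-loop lengths.

    The loop length of node i is the length of the shortest directed cycle
    through i.  Nodes on no cycle contribute zero reciprocal, mirroring the
    infinite-distance convention of :func:`harmonic_path_length`; a fully
    acyclic graph yields ``inf``.
    """
    n = graph.n_nodes
    d = _distance_matrix(graph)
    lts = np.full(n, np.inf)
    a = graph.adjacency
    for i in range(n):
        succ = np.flatnonzero(a[i])
        if len(succ):
            lts[i] = 1.0 + d[succ, i].min()
    recip = np.where(np.isfinite(lts), 1.0 / lts, 0.0)
    total = recip.sum()
    if total == 0:
        return np.inf
    return float(n / total)


# ---------------------------------------------------------------------------
# degree statistics and spectrum
# ---------------------------------------------------------------------------
def out_degree_deviation(graph: DirectedGraph) -> float:
    """Sample standard deviation (n - 1 denominator) of realized out-degrees."""
    if graph.n_nodes < 2:
        raise ValueError("out-degree deviation needs at least two nodes")
    return float(np.std(graph.out_degrees(), ddof=1))


def degree_correlation(graph: DirectedGraph) -> tuple[float, bool]:
    """Pearson correlation between realized in- and out-degrees.

    Returns ``(value, defined)``; for a constant degree vector the
    correlation is undefined and the sentinel ``(0.0, False)`` is returned.
    """
    din = graph.in_degrees().astype(float)
    dout = graph.out_degrees().astype(float)
    if din.std() == 0 or dout.std() == 0:
        return 0.0, False
    return float(np.corrcoef(din, dout)[0, 1]), True


def max_eigenvalue(graph: DirectedGraph) -> float:
    """Spectral radius of the binary adjacency (the Perron root)."""
    if graph.n_edges == 0:
        return 0.0
    ev = np.linalg.eigvals(graph.adjacency.astype(np.float64))
    return float(np.abs(ev).max())


# ---------------------------------------------------------------------------
# triad motif census
# ---------------------------------------------------------------------------
@lru_cache(maxsize=1)
def _triad_code_table() -> np.ndarray:
    """Map each 6-bit induced-subgraph code to a motif index (1..13, 0 = unconnected).

    Bit order for a triple (i, j, k):
    ``i->j, j->i, i->k, k->i, j->k, k->j``.
    """
    table = np.zeros(64, dtype=np.int8)
    pos = {name: idx + 1 for idx, name in enumerate(MOTIF_ORDER)}
    bits = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    for code in range(64):
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        for b, (u, v) in enumerate(bits):
            if code >> b & 1:
                g.add_edge(u, v)
        name = nx.triad_type(g)
        table[code] = pos.get(name, 0)
    return table


@njit(cache=True)
def _census_kernel(adj, table):  # pragma: no cover - exercised via motif_counts
    counts = np.zeros(14, dtype=np.int64)
    n = adj.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                code = (
                    adj[i, j]
                    | adj[j, i] << 1
                    | adj[i, k] << 2
                    | adj[k, i] << 3
                    | adj[j, k] << 4
                    | adj[k, j] << 5
                )
                counts[table[code]] += 1
    return counts


def motif_counts(graph: DirectedGraph) -> np.ndarray:
    """Census of the 13 connected 3-node motifs over all unordered triples."""
    if graph.n_nodes < 3:
        raise ValueError("motif census needs at least three nodes")
    adj = graph.adjacency.astype(np.uint8)
    counts = _census_kernel(adj, _triad_code_table())
    return counts[1:].copy()


# ---------------------------------------------------------------------------
# the full feature vector
# ---------------------------------------------------------------------------
@dataclass
class GraphMeasures:
    """The 21-entry structural feature vector of one network."""

    cc: float
    pl: float
    nb: float
    od: float
    dc: float
    lts: float
    meig: float
    mot: np.ndarray
    mean_degree: float
    cc_std: float = np.nan  # std of local clustering over eligible nodes
    dc_defined: bool = True

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.cc, self.pl, self.nb, self.od, self.dc, self.lts, self.meig],
             self.mot.astype(float), [self.mean_degree]]
        )

    @staticmethod
    def names() -> tuple[str, ...]:
        return MEASURE_NAMES

    def as_dict(self) -> dict:
        d = dict(zip(MEASURE_NAMES, self.to_vector()))
        d["CCstd"] = self.cc_std
        return d


def compute_measures(graph: DirectedGraph) -> GraphMeasures:
    """Compute the full structural feature vector of ``graph``."""
    cc_local, eligible = local_clustering(graph)
    cc = float(cc_local[eligible].mean()) if eligible.any() else 0.0
    cc_std = float(np.std(cc_local[eligible], ddof=1)) if eligible.sum() > 1 else np.nan
    dc, dc_def = degree_correlation(graph)
    return GraphMeasures(
        cc=cc,
        pl=harmonic_path_length(graph),
        nb=node_betweenness(graph),
        od=out_degree_deviation(graph),
        dc=dc,
        lts=length_to_self(graph),
        meig=max_eigenvalue(graph),
        mot=motif_counts(graph),
        mean_degree=float(graph.in_degrees().mean()),
        cc_std=cc_std,
        dc_defined=dc_def,
    )
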