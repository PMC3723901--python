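"""Directed-network generators with an exactly realized in-degree sequence.

All generators first draw one in-degree per node from a configurable
distribution (binomial or truncated power-law, both with expected mean
``p * (n - 1)``), then wire exactly that many distinct presynaptic partners
to each node.  A continuous *strength* parameter interpolates every class
between strictly random wiring (strength 0) and the class's extreme
structure (strength 1):

``RN``
    strictly random: each node's inputs drawn uniformly without replacement.
``WS1`` / ``WS2``
    Watts-Strogatz-type wiring on a ring (1-D) or torus (2-D) embedding;
    each edge is rewired with probability ``1 - strength`` keeping the
    postsynaptic node fixed.  Strength 1 gives the locally connected
    networks ``LCN1`` / ``LCN2``.
``FF``
    feed-forward-motif promotion: when choosing inputs for a node,
    candidates that already project disynaptically to it get a large
    sampling-weight boost, so secured (direct + disynaptic) connections
    accumulate.
``L2``/``L3``/``L4``/``L6``
    loop promotion: edges are added one by one; a candidate presynaptic
    node at geodesic distance ``k - 1`` from the postsynaptic node closes a
    loop of exactly length ``k`` and is boosted, while candidates that would
    create a shorter feedback loop are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .graph import DirectedGraph, EXCITATORY, INHIBITORY

__all__ = [
    "InDegreeSpec",
    "NetworkRecipe",
    "GRAPH_CLASSES",
    "sample_in_degrees",
    "generate_random",
    "generate_ws",
    "generate_ff",
    "generate_loopy",
    "assign_populations",
    "excitatory_subgraph",
]

#: weight boost given to favoured candidates in the FF and loopy schemes
W_BOOST = 50.0
#: residual weight of loop-shortening candidates at strength 1
EPS_SHORTEN = 1e-3

GRAPH_CLASSES = ("RN", "WS1", "WS2", "FF", "L2", "L3", "L4", "L6", "LCN1", "LCN2")


# ---------------------------------------------------------------------------
# in-degree distributions
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class InDegreeSpec:
    """In-degree law with expected mean ``connection_probability * (n - 1)``.

    ``binomial`` draws ``Bin(n - 1, p)`` (one trial per potential
    presynaptic partner, self-connections excluded).  ``powerlaw`` draws
    from the truncated discrete law ``P(k) ~ k**(-alpha)`` on
    ``[min_degree, n - 1]`` with the exponent solved numerically so the
    exact mean equals ``p * (n - 1)``.  ``explicit`` uses a user-given
    sequence verbatim.
    """

    shape: str = "binomial"
    connection_probability: float = 0.2
    n_nodes: int = 100
    min_degree: int = 2
    degrees: tuple | None = None  # for shape="explicit"

    def __post_init__(self):
        if self.shape not in ("binomial", "powerlaw", "explicit"):
            raise ValueError(f"unknown in-degree shape {self.shape!r}")
        if self.shape != "explicit" and not (0 < self.connection_probability < 1):
            raise ValueError("connection_probability must lie in (0, 1)")
        if self.n_nodes < 2:
            raise ValueError("need at least two nodes")

    @property
    def target_mean(self) -> float:
        return self.connection_probability * (self.n_nodes - 1)

    def powerlaw_exponent(self) -> float:
        """Exponent alpha with exact distribution mean ``p * (n - 1)``."""
        return _solve_powerlaw_exponent(self.min_degree, self.n_nodes - 1, self.target_mean)

    def pmf_support(self) -> tuple[np.ndarray, np.ndarray]:
        """Support and pmf of the power-law in-degree distribution."""
        if self.shape != "powerlaw":
            raise ValueError("pmf_support is defined for the powerlaw shape only")
        k = np.arange(self.min_degree, self.n_nodes)
        w = k.astype(float) ** (-self.powerlaw_exponent())
        return k, w / w.sum()


def _truncated_powerlaw_mean(alpha: float, kmin: int, kmax: int) -> float:
    k = np.arange(kmin, kmax + 1, dtype=float)
    logw = -alpha * np.log(k)
    w = np.exp(logw - logw.max())
    return float((k * w).sum() / w.sum())


def _solve_powerlaw_exponent(kmin: int, kmax: int, target: float) -> float:
    if not (kmin < target < kmax):
        raise ValueError(
            f"target mean in-degree {target:.3g} is not attainable on the "
            f"power-law support [{kmin}, {kmax}]"
        )
    # mean is strictly decreasing in alpha; bracket and solve
    lo, hi = -10.0, 50.0
    f = lambda a: _truncated_powerlaw_mean(a, kmin, kmax) - target
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def sample_in_degrees(spec: InDegreeSpec, rng_seed: int) -> np.ndarray:
    """Draw one in-degree per node; reproducible under a fixed seed."""
    rng = np.random.default_rng(rng_seed)
    n = spec.n_nodes
    if spec.shape == "explicit":
        deg = np.asarray(spec.degrees, dtype=np.int64)
        if len(deg) != n or deg.min() < 0 or deg.max() > n - 1:
            raise ValueError("explicit degree sequence invalid")
        return deg
    if spec.shape == "binomial":
        return rng.binomial(n - 1, spec.connection_probability, size=n).astype(np.int64)
    support, pmf = spec.pmf_support()
    return rng.choice(support, size=n, p=pmf).astype(np.int64)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------
def _check_degrees(degrees: np.ndarray) -> np.ndarray:
    degrees = np.asarray(degrees, dtype=np.int64)
    n = len(degrees)
    if degrees.min() < 0 or degrees.max() > n - 1:
        raise ValueError("each in-degree must lie in [0, n - 1]")
    return degrees


def generate_random(degrees, rng_seed: int) -> DirectedGraph:
    """Strictly random wiring: uniform presynaptic partners, no repeats."""
    degrees = _check_degrees(degrees)
    n = len(degrees)
    rng = np.random.default_rng(rng_seed)
    adj = np.zeros((n, n), dtype=bool)
    all_nodes = np.arange(n)
    for i in range(n):
        candidates = np.delete(all_nodes, i)
        pre = rng.choice(candidates, size=degrees[i], replace=False)
        adj[pre, i] = True
    return DirectedGraph(adj, meta={"class": "RN"})


def _ring_positions(n: int) -> np.ndarray:
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([np.cos(t), np.sin(t)])


def _torus_positions(n: int) -> np.ndarray:
    s = round(np.sqrt(n))
    if s * s != n:
        raise ValueError("torus embedding requires a perfect-square node count")
    x, y = np.divmod(np.arange(n), s)
    tx = 2 * np.pi * x / s
    ty = 2 * np.pi * y / s
    return np.column_stack([np.cos(tx), np.sin(tx), np.cos(ty), np.sin(ty)])


def generate_ws(degrees, dim: int, strength: float, rng_seed: int) -> DirectedGraph:
    """Watts-Strogatz-type generator on a ring (dim 1) or torus (dim 2).

    Each node is first wired to its spatially nearest nodes (Euclidean
    metric in the embedding, ties broken by lowest node index), then every
    edge is independently rewired with probability ``1 - strength``; the
    postsynaptic node is held fixed and the new presynaptic node is drawn
    uniformly among non-self, non-duplicate candidates.
    """
    degrees = _check_degrees(degrees)
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    n = len(degrees)
    pos = _ring_positions(n) if dim == 1 else _torus_positions(n)
    rng = np.random.default_rng(rng_seed)
    p_rw = 1.0 - strength

    d2 = ((pos[None, :, :] - pos[:, None, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    # stable sort => distance ties broken by lowest node index
    order = np.argsort(np.round(d2, 12), axis=1, kind="stable")

    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        adj[order[i, : degrees[i]], i] = True

    if p_rw > 0:
        pre_all, post_all = np.nonzero(adj)
        rewire = rng.random(len(pre_all)) < p_rw
        for e in np.flatnonzero(rewire):
            j, i = pre_all[e], post_all[e]
            adj[j, i] = False
            while True:  # redraw on self/duplicate collisions
                new = rng.integers(n)
                if new != i and not adj[new, i]:
                    break
            adj[new, i] = True
    return DirectedGraph(adj, positions=pos, meta={"class": f"WS{dim}", "strength": strength})


def _weighted_pick(rng: np.random.Generator, weights: np.ndarray) -> int:
    total = weights.sum()
    return int(np.searchsorted(np.cumsum(weights), rng.random() * total, side="right"))


def generate_ff(degrees, strength: float, rng_seed: int, w_boost: float = W_BOOST) -> DirectedGraph:
    """Promote feed-forward motifs.

    Inputs are selected sequentially per node (nodes visited in random
    order).  While filling node ``i``, a candidate ``j`` that already
    projects disynaptically to ``i`` (a 2-step path ``j -> m -> i`` in the
    current partial graph) carries sampling weight ``1 + strength * w_boost``,
    all other candidates weight 1; sampling is without replacement.
    """
    degrees = _check_degrees(degrees)
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    n = len(degrees)
    rng = np.random.default_rng(rng_seed)
    adj = np.zeros((n, n), dtype=bool)
    boost = strength * w_boost
    for i in rng.permutation(n):
        # disynaptic projectors to i: any j with j -> m and m -> i
        disyn = adj[:, adj[:, i]].any(axis=1)
        for _ in range(degrees[i]):
            w = np.ones(n)
            if boost:
                w[disyn] += boost
            w[i] = 0.0
            w[adj[:, i]] = 0.0
            j = _weighted_pick(rng, w)
            adj[j, i] = True
            disyn |= adj[:, j]  # j's presynaptic partners now project disynaptically
    return DirectedGraph(adj, meta={"class": "FF", "strength": strength})


def _distances_from(adj: np.ndarray, source: int, max_depth: int) -> np.ndarray:
    """BFS distances from ``source`` along edge direction, truncated at max_depth."""
    n = adj.shape[0]
    dist = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    dist[source] = 0
    frontier = np.zeros(n, dtype=bool)
    frontier[source] = True
    seen = frontier.copy()
    for d in range(1, max_depth + 1):
        frontier = adj[frontier].any(axis=0) & ~seen
        if not frontier.any():
            break
        dist[frontier] = d
        seen |= frontier
    return dist


def generate_loopy(
    degrees,
    loop_length: int,
    strength: float,
    rng_seed: int,
    w_boost: float = W_BOOST,
    eps: float = EPS_SHORTEN,
) -> DirectedGraph:
    """Promote directed feedback loops of length ``loop_length``.

    Edges are added one at a time until every node has its drawn in-degree,
    visiting nodes in random order and filling each node's inputs
    sequentially.  Choosing presynaptic ``j`` for node ``i``, the weight
    depends on the current geodesic distance ``d(i -> j)``: if
    ``d(i -> j) + 1`` is a multiple of ``loop_length`` the new edge closes
    a feedback loop of the promoted length (the congruence keeps emergent
    layer structure consistent) and ``j`` is boosted by ``strength *
    w_boost``; any other finite distance means the edge would create a
    loop of a discredited length and ``j`` is suppressed towards a residual
    weight ``eps``; unreachable candidates keep weight 1.  If the drawn
    degrees are too large, excess edges must create short-cuts through the
    promoted loops, so the loop structure is sharpest at low density.
    """
    if loop_length not in (2, 3, 4, 6):
        raise ValueError("loop_length must be one of 2, 3, 4, 6")
    degrees = _check_degrees(degrees)
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    n = len(degrees)
    rng = np.random.default_rng(rng_seed)
    adj = np.zeros((n, n), dtype=bool)
    boost = strength * w_boost
    # weight of loop-shortening candidates: 1 at strength 0 (random limit),
    # ~eps at strength 1
    w_shorten = (1.0 - strength) + eps * strength
    max_depth = 2 * loop_length
    inf = np.iinfo(np.int64).max
    for i in rng.permutation(n):
        for _ in range(degrees[i]):
            dist = _distances_from(adj, i, max_depth)
            finite = dist < inf
            at_target = finite & (dist % loop_length == loop_length - 1)
            too_close = finite & (dist > 0) & ~at_target
            w = np.ones(n)
            w[at_target] += boost
            w[too_close] = w_shorten
            w[i] = 0.0
            w[adj[:, i]] = 0.0
            j = _weighted_pick(rng, w)
            adj[j, i] = True
    return DirectedGraph(adj, meta={"class": f"L{loop_length}", "strength": strength})


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------
def assign_populations(
    graph: DirectedGraph, inhibitory_fraction: float = 0.2, rng_seed: int = 0
) -> DirectedGraph:
    """Label ``round(fraction * n)`` randomly picked nodes as inhibitory."""
    if graph.labels is not None:
        raise ValueError("population labels already set")
    if not 0 <= inhibitory_fraction < 1:
        raise ValueError("inhibitory_fraction must lie in [0, 1)")
    n = graph.n_nodes
    rng = np.random.default_rng(rng_seed)
    labels = np.full(n, EXCITATORY, dtype=np.int8)
    n_inh = round(inhibitory_fraction * n)
    labels[rng.choice(n, size=n_inh, replace=False)] = INHIBITORY
    return DirectedGraph(graph.adjacency, positions=graph.positions, labels=labels,
                         meta=dict(graph.meta))


def excitatory_subgraph(graph: DirectedGraph) -> DirectedGraph:
    """Induced subgraph on the excitatory population, re-indexed contiguously."""
    if graph.labels is None:
        raise ValueError("graph has no population labels")
    ids = graph.excitatory_ids()
    sub = graph.adjacency[np.ix_(ids, ids)]
    pos = graph.positions[ids] if graph.positions is not None else None
    meta = dict(graph.meta)
    meta["parent_ids"] = ids
    return DirectedGraph(sub, positions=pos, meta=meta)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class NetworkRecipe:
    """Generative specification that fully determines a graph ensemble."""

    graph_class: str
    strength: float
    in_degree: InDegreeSpec
    seed: int = 0

    def __post_init__(self):
        if self.graph_class not in GRAPH_CLASSES:
            raise ValueError(f"unknown graph class {self.graph_class!r}")
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must lie in [0, 1]")

    @property
    def name(self) -> str:
        if self.graph_class in ("RN", "LCN1", "LCN2"):
            return self.graph_class
        return f"{self.graph_class}_s{self.strength:g}"

    def generate(self, rng_seed: int | None = None) -> DirectedGraph:
        seed = self.seed if rng_seed is None else rng_seed
        ss = np.random.SeedSequence(seed)
        deg_seed, wire_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        degrees = sample_in_degrees(self.in_degree, deg_seed)
        cls, s = self.graph_class, self.strength
        if cls == "RN":
            g = generate_random(degrees, wire_seed)
        elif cls in ("WS1", "LCN1"):
            g = generate_ws(degrees, 1, 1.0 if cls == "LCN1" else s, wire_seed)
        elif cls in ("WS2", "LCN2"):
            g = generate_ws(degrees, 2, 1.0 if cls == "LCN2" else s, wire_seed)
        elif cls == "FF":
            g = generate_ff(degrees, s, wire_seed)
        else:  # L2/L3/L4/L6
            g = generate_loopy(degrees, int(cls[1]), s, wire_seed)
        g.meta.update(recipe=self.name, seed=seed)
        return g

    def with_seed(self, seed: int) -> "NetworkRecipe":
        return replace(self, seed=seed)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "graph_class": self.graph_class,
            "strength": self.strength,
            "seed": self.seed,
            "shape": self.in_degree.shape,
            "n_nodes": self.in_degree.n_nodes,
        }
        if self.in_degree.shape == "explicit":
            d["degrees"] = list(self.in_degree.degrees)
        else:
            d["connection_probability"] = self.in_degree.connection_probability
            if self.in_degree.shape == "powerlaw":
                d["min_degree"] = self.in_degree.min_degree
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkRecipe":
        spec = InDegreeSpec(
            shape=d["shape"],
            connection_probability=d.get("connection_probability", 0.2),
            n_nodes=d["n_nodes"],
            min_degree=d.get("min_degree", 2),
            degrees=tuple(d["degrees"]) if "degrees" in d else None,
        )
        return cls(d["graph_class"], d["strength"], spec, d.get("seed", 0))

    def save(self, path) -> None:
        """Write the recipe as a YAML mapping."""
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "NetworkRecipe":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
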