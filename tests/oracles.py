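"""Independent brute-force reference implementations for small graphs.

Everything here is deliberately naive — exhaustive enumeration over node
tuples, pure-python BFS, permutation enumeration — and shares no code with
the package, so it can serve as an oracle for the optimized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = len(adj)
    dist = np.full(n, np.inf)
    dist[source] = 0
    queue = [source]
    while queue:
        u = queue.pop(0)
        for v in range(n):
            if adj[u][v] and dist[v] == np.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def clustering_oracle(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Directed clustering by exhaustive enumeration of directed triangles.

    For node i, count ordered neighbor pairs (j, k) forming a directed
    3-cycle i->j->k->i over all orientation combinations; this equals the
    Fagiolo count (A+A^T)^3_ii / 2.  Normalize by the count attainable in a
    fully bidirectional neighborhood: d_tot(d_tot - 1) - 2 d_bidir.
    """
    n = len(adj)
    a = adj.astype(int)
    cc = np.zeros(n)
    for i in range(n):
        tri = 0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) < 3:
                    continue
                # each directed triangle through i in either rotational sense
                tri += (a[i][j] + a[j][i]) * (a[j][k] + a[k][j]) * (a[k][i] + a[i][k])
        tri /= 2.0  # (j, k) and (k, j) double-count each triangle
        d_tot = a[i].sum() + a[:, i].sum()
        d_bi = sum(a[i][j] and a[j][i] for j in range(n))
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        cc[i] = tri / denom if denom > 0 else 0.0
    neighbors = ((a + a.T) > 0).sum(axis=1)
    eligible = neighbors > 1
    net = cc[eligible].mean() if eligible.any() else 0.0
    return cc, float(net)


def harmonic_path_length_oracle(adj: np.ndarray) -> float:
    n = len(adj)
    total = 0.0
    for s in range(n):
        dist = bfs_distances(adj, s)
        for t in range(n):
            if t != s and np.isfinite(dist[t]):
                total += 1.0 / dist[t]
    return n * (n - 1) / total if total > 0 else np.inf


def _all_geodesics(adj: np.ndarray, s: int, t: int) -> list[tuple]:
    """All shortest directed paths from s to t (tuples of nodes)."""
    dist = bfs_distances(adj, s)
    if not np.isfinite(dist[t]):
        return []
    paths = [[s]]
    for step in range(int(dist[t])):
        nxt = []
        for p in paths:
            u = p[-1]
            for v in range(len(adj)):
                if adj[u][v] and dist[v] == dist[u] + 1:
                    nxt.append(p + [v])
        paths = nxt
    return [tuple(p) for p in paths if p[-1] == t]


def node_betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    nb = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        paths = _all_geodesics(adj, s, t)
        if not paths:
            continue
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            nb[i] += through / len(paths)
    return nb


def length_to_self_oracle(adj: np.ndarray) -> float:
    n = len(adj)
    total = 0.0
    for i in range(n):
        best = np.inf
        for j in range(n):
            if adj[i][j]:
                d = bfs_distances(adj, j)[i]
                best = min(best, 1.0 + d)
        if np.isfinite(best):
            total += 1.0 / best
    return n / total if total > 0 else np.inf


# ---------------------------------------------------------------------------
# motif census by per-triple isomorphism matching
# ---------------------------------------------------------------------------
def _canonical(sub: np.ndarray) -> int:
    best = -1
    for perm in itertools.permutations(range(3)):
        code = 0
        bit = 0
        for a in range(3):
            for b in range(3):
                if a == b:
                    continue
                if sub[perm[a]][perm[b]]:
                    code |= 1 << bit
                bit += 1
        best = max(best, code)
    return best


def _motif_prototypes(order) -> dict[int, int]:
    """Canonical code -> motif index for the given triad-name ordering."""
    edges = {
        "021D": [(1, 0), (1, 2)],
        "021U": [(0, 1), (2, 1)],
        "021C": [(0, 1), (1, 2)],
        "111D": [(0, 1), (1, 0), (2, 1)],
        "111U": [(0, 1), (1, 0), (1, 2)],
        "030T": [(0, 1), (1, 2), (0, 2)],
        "030C": [(0, 1), (1, 2), (2, 0)],
        "201": [(0, 1), (1, 0), (1, 2), (2, 1)],
        "120D": [(0, 1), (0, 2), (1, 2), (2, 1)],
        "120U": [(1, 0), (2, 0), (1, 2), (2, 1)],
        "120C": [(0, 1), (1, 2), (0, 2), (2, 0)],
        "210": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2)],
        "300": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)],
    }
    table = {}
    for idx, name in enumerate(order):
        sub = np.zeros((3, 3), dtype=int)
        for u, v in edges[name]:
            sub[u][v] = 1
        table[_canonical(sub)] = idx
    return table


def motif_census_oracle(adj: np.ndarray, order) -> np.ndarray:
    protos = _motif_prototypes(order)
    counts = np.zeros(len(order), dtype=np.int64)
    n = len(adj)
    for i, j, k in itertools.combinations(range(n), 3):
        sub = adj[np.ix_([i, j, k], [i, j, k])].astype(int)
        und = sub + sub.T
        # weak connectivity of the triple
        deg = (und > 0).sum(axis=1)
        if (deg == 0).any() or (und > 0).sum() // 2 < 2:
            continue
        counts[protos[_canonical(sub)]] += 1
    return counts


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------
def mann_whitney_exact_oracle(a, b) -> float:
    """Exact two-sided Mann-Whitney p-value by exhaustive label permutation."""
    a, b = list(a), list(b)
    n_a = len(a)
    pooled = a + b

    def u_stat(sample_a, sample_b):
        u = 0.0
        for x in sample_a:
            for y in sample_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = u_stat(a, b)
    mean_u = n_a * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(sa, sb)
        total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


def ols_normal_equations_oracle(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(design.T @ design) @ design.T @ y
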