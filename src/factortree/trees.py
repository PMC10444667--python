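"""Spanning trees over items: the residual (Markov-tree) dependence structure."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VineTree",
    "max_spanning_tree",
    "prim_mst",
    "tree_path",
    "read_edge_list",
    "write_edge_list",
]

log = logging.getLogger("factortree")

Edge = Tuple[int, int]


def _norm_edge(e) -> Edge:
    j, k = int(e[0]), int(e[1])
    if j == k:
        raise ValueError(f"self-loop edge ({j}, {k})")
    return (j, k) if j < k else (k, j)


@dataclass(frozen=True)
class VineTree:
    """A spanning tree (or the empty tree) on d items; edges are 0-based pairs.

    A nonempty edge set must have d - 1 edges forming a connected acyclic
    graph; an empty edge set denotes a pure factor model.
    """

    d: int
    edges: Tuple[Edge, ...] = ()

    def __post_init__(self):
        edges = tuple(sorted(_norm_edge(e) for e in self.edges))
        object.__setattr__(self, "edges", edges)
        if not edges:
            return
        if len(set(edges)) != len(edges):
            raise ValueError("duplicate edges")
        for j, k in edges:
            if not (0 <= j < self.d and 0 <= k < self.d):
                raise ValueError(f"edge ({j}, {k}) out of range for d={self.d}")
        if len(edges) != self.d - 1 or not self._connected():
            raise ValueError("edge set must form a spanning tree (d-1 edges, connected)")

    def _connected(self) -> bool:
        parent = list(range(self.d))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for j, k in self.edges:
            rj, rk = find(j), find(k)
            if rj == rk:
                return False
            parent[rj] = rk
        return True

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, j: int) -> List[int]:
        out = []
        for a, b in self.edges:
            if a == j:
                out.append(b)
            elif b == j:
                out.append(a)
        return sorted(out)

    def bfs_order(self) -> List[Tuple[int, Optional[int]]]:
        """Breadth-first (node, parent) order from the lowest-index node."""
        if not self.edges:
            return [(j, None) for j in range(self.d)]
        root = 0
        seen = {root}
        order: List[Tuple[int, Optional[int]]] = [(root, None)]
        frontier = [root]
        while frontier:
            nxt = []
            for u in frontier:
                for v in self.neighbors(u):
                    if v not in seen:
                        seen.add(v)
                        order.append((v, u))
                        nxt.append(v)
            frontier = nxt
        if len(seen) != self.d:
            raise ValueError("tree does not span all items")
        return order


def tree_path(tree: VineTree, j: int, k: int) -> List[Edge]:
    """Edges on the unique path between items j and k."""
    adj = {i: tree.neighbors(i) for i in range(tree.d)}
    prev = {j: None}
    frontier = [j]
    while frontier and k not in prev:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    nxt.append(v)
        frontier = nxt
    if k not in prev:
        raise ValueError(f"no path between {j} and {k}")
    path = []
    cur = k
    while prev[cur] is not None:
        path.append(_norm_edge((cur, prev[cur])))
        cur = prev[cur]
    return path[::-1]


def prim_mst(weights: np.ndarray) -> List[Edge]:
    """Minimum spanning tree by Prim's algorithm.

    Ties are broken by the lexicographically smallest (j, k) pair so the
    result is deterministic.  -inf weights are allowed and are naturally
    picked first.
    """
    W = np.asarray(weights, dtype=float)
    d = W.shape[0]
    if W.shape != (d, d):
        raise ValueError("weight matrix must be square")
    if d < 2:
        raise ValueError("need at least two items")
    if np.isnan(W).any():
        raise ValueError("NaN weight")
    in_tree = np.zeros(d, dtype=bool)
    in_tree[0] = True
    edges: List[Edge] = []
    while len(edges) < d - 1:
        best = None
        for u in np.flatnonzero(in_tree):
            for v in np.flatnonzero(~in_tree):
                key = (W[u, v], min(u, v), max(u, v))
                if best is None or key < best:
                    best = key
        _, j, k = best
        edges.append((j, k))
        in_tree[j] = in_tree[k] = True
    return sorted(edges)


def max_spanning_tree(R: np.ndarray) -> VineTree:
    """Spanning tree maximizing pairwise dependence.

    Minimizes sum over edges of log(1 - r_jk^2) with Prim's algorithm; a
    perfect correlation (|r| = 1) yields a -inf weight and that edge is
    forced into the tree first, with a warning.
    """
    R = np.asarray(R, dtype=float)
    d = R.shape[0]
    with np.errstate(divide="ignore"):
        W = np.log(1.0 - np.clip(R, -1.0, 1.0) ** 2)
    np.fill_diagonal(W, np.inf)
    if np.isneginf(W[~np.eye(d, dtype=bool)]).any():
        warnings.warn("perfect correlation: edge forced into the spanning tree")
    return VineTree(d, tuple(prim_mst(W)))


def read_edge_list(path, d: int) -> VineTree:
    """Read a residual tree from a two-column text file of 1-based pairs."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected two items per line")
            j, k = int(parts[0]), int(parts[1])
            edges.append((j - 1, k - 1))
    return VineTree(d, tuple(edges))


def write_edge_list(tree: VineTree, path) -> None:
    """Write tree edges as 1-based 'j k' lines."""
    with open(path, "w") as fh:
        for j, k in tree.edges:
            fh.write(f"{j + 1} {k + 1}\n")
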