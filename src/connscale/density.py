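"""MST-backbone density thresholding.

Fixed-density variants of a weighted connectome are built by first
retaining a maximum-weight spanning tree (so the thresholded network stays
connected) and then adding the remaining edges in descending weight order
until the requested density is met. Ties in weight are broken by ascending
node-index pair so the operation is deterministic.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

__all__ = ["mst_backbone", "threshold_to_density"]


def _sorted_edges(weights: np.ndarray) -> List[Tuple[float, int, int]]:
    iu = np.triu_indices(weights.shape[0], 1)
    w = weights[iu]
    present = w > 0
    edges = list(zip(w[present], iu[0][present], iu[1][present]))
    # descending weight; ties broken by ascending (i, j)
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    return edges


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def mst_backbone(weights: np.ndarray) -> List[Tuple[int, int]]:
    """Maximum-weight spanning tree edge set (Kruskal, deterministic ties).

    Returns the N-1 edges, each as an ``(i, j)`` pair with ``i < j``.
    Raises on disconnected input, naming the number of components.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    uf = _UnionFind(n)
    tree = []
    for w, i, j in _sorted_edges(weights):
        if uf.union(int(i), int(j)):
            tree.append((int(i), int(j)))
            if len(tree) == n - 1:
                break
    if len(tree) < n - 1:
        roots = {uf.find(i) for i in range(n)}
        raise ValueError(f"input graph is disconnected ({len(roots)} components)")
    return tree


def threshold_to_density(weights: np.ndarray, d: float) -> np.ndarray:
    """Threshold to density ``d`` on an MST backbone.

    The output support is the maximum spanning tree plus the remaining
    edges in descending weight order until ``ceil(d * N(N-1)/2)`` edges are
    reached (capped at the available edge count, so ``d = 1`` returns the
    input support). Surviving weights are unchanged.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if not (0 < d <= 1):
        raise ValueError("density d must be in (0, 1]")
    n_target = int(np.ceil(d * n * (n - 1) / 2))
    tree = set(mst_backbone(weights))
    if n_target < len(tree):
        min_d = len(tree) / (n * (n - 1) / 2)
        raise ValueError(
            f"d={d} below the MST-backbone density; minimum achievable is {min_d:.4f}"
        )
    keep = set(tree)
    for w, i, j in _sorted_edges(weights):
        if len(keep) >= n_target:
            break
        keep.add((int(i), int(j)))
    out = np.zeros_like(weights)
    for i, j in keep:
        out[i, j] = weights[i, j]
        out[j, i] = weights[i, j]
    return out
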