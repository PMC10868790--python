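"""Null models certifying that results reflect empirical topology.

Three nulls mirror the three levels of the analysis:

- Mantel-style permutation of a co-classification matrix: rows and columns
  are permuted jointly, preserving the value multiset and symmetry while
  destroying the node correspondence with any other node-pair matrix.
- Module-allegiance permutation of a partition: node labels are shuffled,
  preserving the number and size of modules.
- Distance-binned rewiring of a spatially embedded network: edges are
  split into equal-count Euclidean-distance bins and degree-preserving
  double-edge swaps are applied within bins only, so the degree sequence is
  exactly preserved and geometry is preserved at bin resolution (weights
  travel with their edge).
"""

from __future__ import annotations

import warnings
from typing import Iterator, Sequence, Tuple

import numpy as np

from .bundle import ConnectomeBundle
from .modularity import Partition

__all__ = [
    "permute_cc_mantel",
    "permute_partition_labels",
    "distance_binned_rewire",
]


def permute_cc_mantel(
    cc: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> Iterator[np.ndarray]:
    """Yield jointly row/column-permuted copies of a node-pair matrix."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cc = np.asarray(cc, dtype=float)
    rng = np.random.default_rng(seed)
    n = cc.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yield cc[np.ix_(perm, perm)]


def permute_partition_labels(
    partition: Partition | Sequence[int], seed: int = 0
) -> Partition:
    """Shuffle module allegiance, preserving the module-size multiset."""
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    rng = np.random.default_rng(seed)
    shuffled = labels[rng.permutation(len(labels))]
    gamma = partition.gamma if isinstance(partition, Partition) else np.nan
    return Partition(labels=shuffled, gamma=gamma, q=np.nan)


def distance_binned_rewire(
    bundle: ConnectomeBundle,
    n_bins: int = 10,
    n_swaps: int | None = None,
    seed: int = 0,
    *,
    return_info: bool = False,
):
    """Degree-preserving rewiring restricted to Euclidean-distance bins.

    Existing edges are sorted by Euclidean distance and split into
    ``n_bins`` equal-count bins. Within each bin, double-edge swaps
    ((a,b),(c,d) -> (a,d),(c,b)) are attempted ``n_swaps`` times (default
    10x the bin's edge count); a swap is accepted only if it creates no
    self-loop or duplicate edge. Weights travel with their edge. Returns
    the rewired weight matrix (and, with ``return_info``, a dict with bin
    edges and per-bin edge counts).
    """
    w = bundle.weights.copy()
    n = w.shape[0]
    ed = bundle.euclidean_distances()
    iu = np.triu_indices(n, 1)
    present = w[iu] > 0
    edges = np.stack([iu[0][present], iu[1][present]], axis=1)
    edge_ed = ed[iu][present]
    if len(edges) < 2:
        raise ValueError("network has too few edges to rewire")

    order = np.argsort(edge_ed, kind="stable")
    bins = np.array_split(order, n_bins)
    rng = np.random.default_rng(seed)

    edge_list = [tuple(e) for e in edges]  # (i, j) with i < j, mutable via index
    edge_set = set(edge_list)
    weights_of = {e: w[e] for e in edge_list}

    bin_counts = []
    for b, members in enumerate(bins):
        members = list(members)
        bin_counts.append(len(members))
        if len(members) < 2:
            warnings.warn(f"distance bin {b} has fewer than 2 edges; skipped")
            continue
        attempts = n_swaps if n_swaps is not None else 10 * len(members)
        for _ in range(attempts):
            e1_idx, e2_idx = rng.choice(len(members), size=2, replace=False)
            a, b1 = edge_list[members[e1_idx]]
            c, d = edge_list[members[e2_idx]]
            if rng.uniform() < 0.5:
                new1, new2 = (a, d), (c, b1)
            else:
                new1, new2 = (a, c), (b1, d)
            new1 = (min(new1), max(new1))
            new2 = (min(new2), max(new2))
            if new1[0] == new1[1] or new2[0] == new2[1]:
                continue
            if new1 == new2 or new1 in edge_set or new2 in edge_set:
                continue
            old1, old2 = (a, b1), (c, d)
            edge_set.discard(old1)
            edge_set.discard(old2)
            edge_set.add(new1)
            edge_set.add(new2)
            w1, w2 = weights_of.pop(old1), weights_of.pop(old2)
            weights_of[new1], weights_of[new2] = w1, w2
            edge_list[members[e1_idx]] = new1
            edge_list[members[e2_idx]] = new2

    out = np.zeros_like(w)
    for (i, j), val in weights_of.items():
        out[i, j] = out[j, i] = val
    if return_info:
        info = {
            "bin_counts": bin_counts,
            "bin_membership": [[edge_list[idx] for idx in members] for members in bins],
        }
        return out, info
    return out
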