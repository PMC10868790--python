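"""Multiresolution consensus clustering (MRCC) and module-level features.

Community structure is recovered by maximizing modularity

    Q(gamma) = (1 / 2m) * sum_ij [ W_ij - gamma * k_i k_j / 2m ] * delta(sigma_i, sigma_j)

with the configuration-model null P_ij = k_i k_j / 2m and resolution
parameter gamma. A two-step multiresolution sweep first samples gamma
log-uniformly over a wide range to bracket the informative window
[gamma_L, gamma_H] (partitions with between 2 and N/2 modules), then
resamples inside that window. The resulting partition ensemble is condensed
into a co-classification (CC) matrix — the probability that two nodes share
a module across the resolution spectrum — and a consensus partition is
obtained by maximizing modularity on the CC matrix itself.

Modularity maximization itself (Louvain) is delegated to igraph's
``community_multilevel``; Q scoring is implemented here independently and
normalized by total weight 2m (scale-invariant; normalization does not
change the argmax at fixed gamma).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import List, Sequence

import igraph as ig
import numpy as np

__all__ = [
    "Partition",
    "PartitionEnsemble",
    "modularity_score",
    "optimize_partition",
    "mrcc_ensemble",
    "coclassification_matrix",
    "consensus_from_cc",
    "partition_features",
    "interhemispheric_cc",
]


@dataclass
class Partition:
    """A node->module labeling with the resolution and Q it was found at."""

    labels: np.ndarray
    gamma: float
    q: float

    def __post_init__(self) -> None:
        # contiguous labels from 0
        _, self.labels = np.unique(np.asarray(self.labels), return_inverse=True)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class PartitionEnsemble:
    """Partitions across the gamma grid, with the bracketing resolutions."""

    partitions: List[Partition]
    gamma_low: float
    gamma_high: float
    n_nodes: int
    gammas: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.partitions)


def _validate_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(w, w.T):
        raise ValueError("weights must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w


def modularity_score(weights: np.ndarray, labels: Sequence[int], gamma: float = 1.0) -> float:
    """Modularity Q of a partition, normalized by total weight 2m.

    Diagonal terms of the configuration null are included, per the standard
    configuration-model convention.
    """
    w = _validate_weights(weights)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    labels = np.asarray(labels)
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("empty graph: total weight is zero")
    delta = labels[:, None] == labels[None, :]
    return float(((w - gamma * np.outer(k, k) / two_m) * delta).sum() / two_m)


def _to_igraph(weights: np.ndarray) -> ig.Graph:
    w = np.triu(weights, 1)
    rows, cols = np.nonzero(w)
    g = ig.Graph(n=weights.shape[0], edges=list(zip(rows.tolist(), cols.tolist())))
    g.es["weight"] = w[rows, cols].tolist()
    return g


def _louvain_once(graph: ig.Graph, weights_matrix: np.ndarray, gamma: float, seed: int) -> Partition:
    ig.set_random_number_generator(random.Random(int(seed)))
    clustering = graph.community_multilevel(weights="weight", resolution=gamma)
    labels = np.asarray(clustering.membership)
    candidates = [labels, np.zeros(len(labels), dtype=int), np.arange(len(labels))]
    scored = [(modularity_score(weights_matrix, c, gamma), i, c) for i, c in enumerate(candidates)]
    q, _, best = max(scored, key=lambda t: (t[0], -t[1]))
    return Partition(labels=best, gamma=gamma, q=q)


def optimize_partition(
    weights: np.ndarray, gamma: float = 1.0, seed: int = 0, n_restarts: int = 1
) -> Partition:
    """Louvain modularity maximization at resolution ``gamma``.

    Runs ``n_restarts`` seeded restarts and keeps the max-Q partition.
    The one-module and all-singletons baselines are always evaluated too,
    so the result is never worse than either.
    """
    w = _validate_weights(weights)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    graph = _to_igraph(w)
    best = None
    for r in range(n_restarts):
        part = _louvain_once(graph, w, gamma, seed + r)
        if best is None or part.q > best.q:
            best = part
    return best


def mrcc_ensemble(
    weights: np.ndarray,
    n_gamma: int = 500,
    coarse_range: Sequence[float] = (0.01, 10.0),
    seed: int = 0,
) -> PartitionEnsemble:
    """Two-step multiresolution sweep.

    Step 1: ``n_gamma`` log-spaced resolutions over ``coarse_range``, one
    Louvain run each; gamma_L is the smallest resolution whose partition has
    at least 2 modules and gamma_H the largest with at most N/2. Step 2:
    ``n_gamma`` log-spaced resolutions over [gamma_L, gamma_H]; partitions
    whose module count falls outside [2, N/2] are dropped.
    """
    w = _validate_weights(weights)
    n = w.shape[0]
    lo, hi = coarse_range
    if not (0 < lo < hi):
        raise ValueError("coarse_range must be positive and ordered")
    graph = _to_igraph(w)
    gammas_coarse = np.logspace(np.log10(lo), np.log10(hi), n_gamma)
    counts = []
    for i, gamma in enumerate(gammas_coarse):
        part = _louvain_once(graph, w, gamma, seed * 1_000_003 + i)
        counts.append(part.n_modules)
    counts = np.array(counts)
    ok_low = np.nonzero(counts >= 2)[0]
    ok_high = np.nonzero(counts <= n // 2)[0]
    if len(ok_low) == 0:
        raise ValueError(
            "no resolution produced >= 2 modules; widen coarse_range upward"
        )
    gamma_low = float(gammas_coarse[ok_low[0]])
    gamma_high = float(gammas_coarse[ok_high[-1]]) if len(ok_high) else float(gammas_coarse[-1])
    if gamma_high < gamma_low:
        gamma_high = gamma_low

    gammas_fine = np.logspace(np.log10(gamma_low), np.log10(gamma_high), n_gamma)
    partitions = []
    for i, gamma in enumerate(gammas_fine):
        part = _louvain_once(graph, w, gamma, seed * 2_000_003 + i)
        if 2 <= part.n_modules <= n // 2:
            partitions.append(part)
    if not partitions:
        raise ValueError("no partition in the fine sweep satisfied the [2, N/2] module window")
    return PartitionEnsemble(
        partitions=partitions,
        gamma_low=gamma_low,
        gamma_high=gamma_high,
        n_nodes=n,
        gammas=gammas_fine,
    )


def coclassification_matrix(ensemble: PartitionEnsemble | Sequence[Partition]) -> np.ndarray:
    """Co-classification probability matrix over an ensemble.

    ``CC_ij`` is the fraction of ensemble partitions in which nodes i and j
    share a module; symmetric with unit diagonal.
    """
    partitions = ensemble.partitions if isinstance(ensemble, PartitionEnsemble) else list(ensemble)
    if not partitions:
        raise ValueError("empty partition ensemble")
    n = len(partitions[0].labels)
    cc = np.zeros((n, n))
    for part in partitions:
        lab = part.labels
        cc += lab[:, None] == lab[None, :]
    cc /= len(partitions)
    np.fill_diagonal(cc, 1.0)
    return cc


def consensus_from_cc(cc: np.ndarray, seed: int = 0, n_restarts: int = 100) -> Partition:
    """Consensus partition: modularity maximization on the CC matrix.

    Louvain at gamma = 1 on the CC matrix (diagonal zeroed so the graph has
    no self-loops), ``n_restarts`` restarts, max-Q partition returned.
    """
    cc = _validate_weights(cc)
    w = cc.copy()
    np.fill_diagonal(w, 0.0)
    return optimize_partition(w, gamma=1.0, seed=seed, n_restarts=n_restarts)


def partition_features(
    weights: np.ndarray, ed_matrix: np.ndarray, consensus: Partition | np.ndarray
) -> dict:
    """Module-level features of a consensus partition.

    - ``imd`` (intramodule density): mean over non-singleton modules of the
      within-module edge count divided by the number of possible
      within-module pairs.
    - ``longdist_fraction``: of the top-5% longest existing edges (by
      Euclidean distance; count = ceil(0.05 * E), ties broken by ascending
      node pair), the number whose endpoints lie in different modules,
      normalized by the total module count.
    """
    w = _validate_weights(weights)
    labels = consensus.labels if isinstance(consensus, Partition) else np.asarray(consensus)
    n = w.shape[0]
    modules, sizes = np.unique(labels, return_counts=True)
    adj = w > 0

    densities = []
    for m, size in zip(modules, sizes):
        if size < 2:
            continue  # density undefined for singletons
        idx = np.nonzero(labels == m)[0]
        within = adj[np.ix_(idx, idx)]
        n_edges = within.sum() / 2
        densities.append(n_edges / (size * (size - 1) / 2))
    if not densities:
        raise ValueError("all modules are singletons; IMD undefined")
    imd = float(np.mean(densities))

    iu = np.triu_indices(n, 1)
    present = adj[iu]
    ed = np.asarray(ed_matrix, dtype=float)[iu][present]
    ii, jj = iu[0][present], iu[1][present]
    n_edges_total = len(ed)
    n_top = int(np.ceil(0.05 * n_edges_total))
    order = sorted(range(n_edges_total), key=lambda e: (-ed[e], ii[e], jj[e]))
    top = order[:n_top]
    between = sum(1 for e in top if labels[ii[e]] != labels[jj[e]])
    longdist_fraction = float(between / len(modules))

    return {"imd": imd, "longdist_fraction": longdist_fraction}


def interhemispheric_cc(cc: np.ndarray, hemisphere: Sequence[str]) -> float:
    """Interhemispheric co-classification index.

    Mean CC over between-hemisphere node pairs divided by mean CC over
    within-hemisphere pairs (both hemispheres pooled, diagonal excluded).
    """
    cc = _validate_weights(cc)
    hemi = np.asarray(hemisphere)
    left = hemi == hemi[0]
    if left.all() or not left.any():
        raise ValueError("both hemispheres must be non-empty")
    inter_mask = left[:, None] != left[None, :]
    intra_mask = ~inter_mask
    np.fill_diagonal(intra_mask, False)
    intra_mean = cc[intra_mask].mean()
    if intra_mean == 0:
        raise ValueError("degenerate CC: zero intra-hemisphere mean")
    return float(cc[inter_mask].mean() / intra_mean)
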