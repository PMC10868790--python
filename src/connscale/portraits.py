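"""Network portraits, portrait divergence, and representative selection.

A network portrait is a matrix B whose entry B[l, k] counts the nodes that
have exactly k other nodes at (binned) shortest-path distance l. For
weighted networks the continuous distances are discretized into quantile
bins; when several networks are compared, the bin edges are computed once
from the pooled distances of the whole comparison set so that portraits are
directly comparable. Unreachable pairs land in a dedicated overflow bin, so
disconnected graphs remain comparable.

The network portrait divergence (NPD) between two portraits is the base-2
Jensen-Shannon divergence of the joint distributions over (distance bin,
neighbor count), where each cell is weighted by the number of node pairs it
represents: P(l, k) proportional to k * B[l, k]. NPD is symmetric, zero on
identical portraits and bounded in [0, 1].

Representative-network ("centroid") selection picks, among repeated
instantiations of the same animal, the one with minimal mean NPD to all
others after discarding outliers (mean distance more than 3 scaled median
absolute deviations above the median).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import rel_entr

from .communication import shortest_path_lengths

__all__ = [
    "Portrait",
    "DistanceSummary",
    "quantile_bin_edges",
    "compute_portrait",
    "portrait_divergence",
    "pairwise_npd",
    "select_representative",
    "flag_cohort_outliers",
    "scaled_mad_flags",
]

MAD_SCALE = 1.4826  # consistency constant for normally distributed data
N_QUANTILE_BINS = 25


@dataclass
class Portrait:
    """Binned shortest-path-distance histogram matrix."""

    b: np.ndarray  # (n_bins + overflow) x (N + 1)
    bin_edges: np.ndarray
    n_nodes: int


@dataclass
class DistanceSummary:
    """Pairwise NPD matrix with per-item means and outlier flags."""

    npd: np.ndarray
    mean_distance: np.ndarray
    outlier: np.ndarray


def _finite_offdiag(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vals = dist[mask]
    return vals[np.isfinite(vals)]


def quantile_bin_edges(
    distance_matrices: Sequence[np.ndarray], n_bins: int = N_QUANTILE_BINS
) -> np.ndarray:
    """Quantile bin edges over the pooled finite off-diagonal distances."""
    pooled = np.concatenate([_finite_offdiag(d) for d in distance_matrices])
    if pooled.size == 0:
        raise ValueError("no finite distances to bin")
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[-1] = np.nextafter(edges[-1], np.inf)  # make last bin right-inclusive
    return edges


def compute_portrait(
    weights_or_distances: np.ndarray,
    bin_edges: Optional[np.ndarray] = None,
    *,
    is_distance: bool = False,
) -> Portrait:
    """Build the binned portrait of a weighted network.

    Weighted shortest-path distances (edge length = 1/weight) are computed
    unless ``is_distance`` marks the input as a precomputed distance matrix.
    Pass shared ``bin_edges`` when the portrait will be compared with others;
    otherwise 25 per-network quantile bins are used. Unreachable pairs go to
    one overflow bin beyond the last edge.
    """
    arr = np.asarray(weights_or_distances, dtype=float)
    if arr.size == 0:
        raise ValueError("empty graph")
    dist = arr if is_distance else shortest_path_lengths(arr)
    n = dist.shape[0]
    if bin_edges is None:
        bin_edges = quantile_bin_edges([dist])
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(bin_edges) < 0):
            raise ValueError("bin_edges must be non-decreasing")
    n_bins = len(bin_edges) - 1
    b = np.zeros((n_bins + 1, n + 1), dtype=int)  # last row = overflow (incl. unreachable)
    offdiag = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = dist[i][offdiag[i]]
        binned = np.digitize(row, bin_edges[1:], right=False)  # 0..n_bins
        binned = np.where(np.isfinite(row), np.minimum(binned, n_bins), n_bins)
        counts = np.bincount(binned, minlength=n_bins + 1)
        for l, k in enumerate(counts):
            b[l, k] += 1
    return Portrait(b=b, bin_edges=bin_edges, n_nodes=n)


def _joint_distribution(portrait: Portrait) -> np.ndarray:
    k = np.arange(portrait.b.shape[1])
    weighted = portrait.b * k[None, :]
    total = weighted.sum()
    if total == 0:
        raise ValueError("portrait encodes no node pairs")
    return weighted / total


def portrait_divergence(a: Portrait, b: Portrait) -> float:
    """Base-2 Jensen-Shannon divergence between two portraits, in [0, 1]."""
    if a.bin_edges.shape != b.bin_edges.shape or not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("portraits must share bin_edges to be comparable")
    pa, pb = _joint_distribution(a), _joint_distribution(b)
    rows = max(pa.shape[0], pb.shape[0])
    cols = max(pa.shape[1], pb.shape[1])
    qa = np.zeros((rows, cols))
    qb = np.zeros((rows, cols))
    qa[: pa.shape[0], : pa.shape[1]] = pa
    qb[: pb.shape[0], : pb.shape[1]] = pb
    m = (qa + qb) / 2.0
    jsd = 0.5 * rel_entr(qa, m).sum() + 0.5 * rel_entr(qb, m).sum()
    return float(jsd / np.log(2))


def pairwise_npd(weight_matrices: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Pairwise NPD matrix over networks, with shared pooled bin edges."""
    dists = [shortest_path_lengths(w) for w in weight_matrices]
    edges = quantile_bin_edges(dists)
    portraits = [compute_portrait(d, edges, is_distance=True) for d in dists]
    m = len(portraits)
    npd = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            npd[i, j] = npd[j, i] = portrait_divergence(portraits[i], portraits[j])
    return npd, edges


def scaled_mad_flags(values: np.ndarray, n_mads: float = 3.0) -> np.ndarray:
    """Flag values above median + n_mads * scaled MAD."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = MAD_SCALE * np.median(np.abs(values - med))
    return values > med + n_mads * mad


def select_representative(instances: Sequence[np.ndarray]) -> Tuple[int, DistanceSummary]:
    """Pick the centroid instantiation by minimal mean portrait divergence.

    Instances whose mean distance exceeds the median by more than 3 scaled
    MADs are discarded as outliers; among the survivors, the index of the
    minimal mean distance (recomputed over survivors) is returned. Ties go
    to the lowest index.
    """
    if len(instances) < 2:
        raise ValueError("need at least 2 instances")
    npd, _ = pairwise_npd(instances)
    m = npd.shape[0]
    mean_dist = npd.sum(axis=1) / (m - 1)
    outlier = scaled_mad_flags(mean_dist)
    if outlier.all():
        raise ValueError("degenerate ensemble: every instance flagged as outlier")
    survivors = np.nonzero(~outlier)[0]
    if len(survivors) == 1:
        best = int(survivors[0])
    else:
        sub = npd[np.ix_(survivors, survivors)]
        sub_mean = sub.sum(axis=1) / (len(survivors) - 1)
        best = int(survivors[np.argmin(sub_mean)])
    return best, DistanceSummary(npd=npd, mean_distance=mean_dist, outlier=outlier)


def flag_cohort_outliers(
    npd_matrix: np.ndarray, order_labels: Sequence[str]
) -> dict:
    """Flag cohort members that sit too far from the rest.

    Two rules: (1) cohort-mean NPD above median + 3 scaled MADs; (2) within
    own taxonomic order, the total distance to same-order members has a
    z-score above 3. Members of singleton orders are exempt from rule 2
    (z undefined) and listed under ``zscore_exempt``.
    """
    npd = np.asarray(npd_matrix, dtype=float)
    if npd.ndim != 2 or npd.shape[0] != npd.shape[1]:
        raise ValueError("npd_matrix must be square")
    if not np.allclose(npd, npd.T):
        raise ValueError("npd_matrix must be symmetric")
    labels = np.asarray(order_labels)
    m = npd.shape[0]
    if labels.shape != (m,):
        raise ValueError("one order label per item required")

    mean_dist = npd.sum(axis=1) / (m - 1)
    mad_flag = scaled_mad_flags(mean_dist)

    z_flag = np.zeros(m, dtype=bool)
    exempt = np.zeros(m, dtype=bool)
    for order in np.unique(labels):
        idx = np.nonzero(labels == order)[0]
        if len(idx) < 2:
            exempt[idx] = True
            continue
        within = npd[np.ix_(idx, idx)].sum(axis=1)
        sd = within.std(ddof=0)
        if sd == 0:
            continue
        z = (within - within.mean()) / sd
        z_flag[idx] = z > 3.0
    return {
        "flags": mad_flag | z_flag,
        "mad_flags": mad_flag,
        "zscore_flags": z_flag,
        "zscore_exempt": exempt,
        "mean_distance": mean_dist,
    }
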