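"""Network communication models and the routing/diffusion morphospace.

Three models span the routing-to-diffusion spectrum:

- Shortest-path efficiency (SPE): edge weights are converted to lengths
  L = 1/W; the shortest-path length matrix Pi is inverted elementwise,
  SPE = 1/Pi. Communication via selectively accessed optimal routes.
- Search information (SI): the bits a random walker needs to follow the
  shortest path, SI_ij = -log2 P(pi_{i->j}) with transition probabilities
  p_uv = W_uv / s_u. Reported as the symmetric negative search information
  NSI_ij = -(SI_ij + SI_ji)/2, so larger values mean easier communication.
- Communicability (CMY): matrix exponential of the strength-normalized
  weights S^{-1/2} W S^{-1/2}; sums contributions of all walks (diffusive
  broadcasting).

The morphospace places each network in a standardized 2-D space by scaling
its mean SPE and mean CMY relative to ensembles of one-dimensional ring
lattices and random graphs matched in size, edge count and weight multiset:

    X_scaled = (X - <X_latt>) / (<X_rand> - <X_latt>)

so a lattice-like network sits near 0 and a random-like network near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import expm
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "CommunicationSet",
    "MorphospacePoint",
    "shortest_path_lengths",
    "shortest_path_efficiency",
    "search_information",
    "negative_search_information",
    "communicability",
    "communication_set",
    "scaled_morphospace",
]


def _validate(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weights must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w


@dataclass
class CommunicationSet:
    """SPE / NSI / CMY matrices for one network plus a validity mask.

    ``valid`` marks off-diagonal pairs where all three measures are defined
    (connected pairs, no isolated endpoints); the diagonal is always False.
    """

    spe: np.ndarray
    nsi: np.ndarray
    cmy: np.ndarray
    valid: np.ndarray


@dataclass
class MorphospacePoint:
    """Standardized routing/diffusion coordinates for one network."""

    spe_scaled: float
    cmy_scaled: float
    mean_spe: float
    mean_cmy: float
    ref_spe_latt: float
    ref_spe_rand: float
    ref_cmy_latt: float
    ref_cmy_rand: float
    n_realizations: int


def shortest_path_lengths(weights: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path lengths with edge length = 1/weight."""
    w = _validate(weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dijkstra(sp.csr_matrix(lengths), directed=False)


def shortest_path_efficiency(weights: np.ndarray) -> np.ndarray:
    """SPE = 1/Pi elementwise; unreachable pairs get 0, diagonal 0."""
    pi = shortest_path_lengths(weights)
    with np.errstate(divide="ignore"):
        spe = np.where(np.isfinite(pi) & (pi > 0), 1.0 / np.where(pi > 0, pi, 1.0), 0.0)
    np.fill_diagonal(spe, 0.0)
    return spe


def _reconstruct_path(
    i: int, j: int, lengths: np.ndarray, dist: np.ndarray, neighbors: list
) -> list:
    """Lexicographically smallest shortest path from i to j (node sequence)."""
    path = [i]
    u = i
    guard = lengths.shape[0] + 1
    while u != j:
        target = dist[u, j]
        nxt = None
        for v in neighbors[u]:
            if abs(lengths[u, v] + dist[v, j] - target) <= 1e-12 * max(1.0, target):
                nxt = v
                break
        if nxt is None or len(path) > guard:  # numerical dead end; should not happen
            raise RuntimeError(f"shortest-path reconstruction failed for pair ({i}, {j})")
        path.append(nxt)
        u = nxt
    return path


def search_information(weights: np.ndarray) -> np.ndarray:
    """Directed search information SI_ij in bits; NaN for unreachable pairs.

    The shortest path is made unique by a deterministic lexicographic
    tie-break (smallest next node index among ties).
    """
    w = _validate(weights)
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    dist = dijkstra(sp.csr_matrix(np.where(np.isfinite(lengths), lengths, 0.0)), directed=False)
    strength = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        trans = np.where(strength[:, None] > 0, w / strength[:, None], 0.0)
    neighbors = [np.nonzero(w[u] > 0)[0].tolist() for u in range(n)]

    si = np.full((n, n), np.nan)
    np.fill_diagonal(si, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(dist[i, j]):
                continue
            path = _reconstruct_path(i, j, lengths, dist, neighbors)
            logp = 0.0
            for u, v in zip(path[:-1], path[1:]):
                logp += np.log2(trans[u, v])
            si[i, j] = -logp
    return si


def negative_search_information(weights: np.ndarray) -> np.ndarray:
    """Symmetric NSI_ij = -(SI_ij + SI_ji)/2; NaN where no path exists."""
    si = search_information(weights)
    nsi = -(si + si.T) / 2.0
    np.fill_diagonal(nsi, 0.0)
    return nsi


def communicability(weights: np.ndarray, *, literal_strength_product: bool = False) -> np.ndarray:
    """Strength-normalized communicability, CMY = expm(S^{-1/2} W S^{-1/2}).

    Rows/columns of isolated nodes (zero strength) are NaN-masked. With
    ``literal_strength_product=True``, the normalization W_ij / (s_i s_j)
    is used instead of the square-root form.
    """
    w = _validate(weights)
    strength = w.sum(axis=1)
    isolated = strength == 0
    if isolated.all():
        return np.eye(w.shape[0])  # exp(0): no walks anywhere
    s = np.where(isolated, 1.0, strength)
    if literal_strength_product:
        norm = w / np.outer(s, s)
    else:
        inv_sqrt = 1.0 / np.sqrt(s)
        norm = inv_sqrt[:, None] * w * inv_sqrt[None, :]
    cmy = expm(norm)
    if isolated.any():
        cmy[isolated, :] = np.nan
        cmy[:, isolated] = np.nan
    return cmy


def communication_set(weights: np.ndarray) -> CommunicationSet:
    """All three communication matrices plus the shared validity mask."""
    w = _validate(weights)
    spe = shortest_path_efficiency(w)
    nsi = negative_search_information(w)
    cmy = communicability(w)
    valid = np.isfinite(nsi) & np.isfinite(cmy) & (spe > 0)
    np.fill_diagonal(valid, False)
    return CommunicationSet(spe=spe, nsi=nsi, cmy=cmy, valid=valid)


def _ring_lattice_edges(n: int, n_edges: int) -> tuple:
    """First ``n_edges`` node pairs in order of circular distance."""
    rows, cols = [], []
    count = 0
    for d in range(1, n // 2 + 1):
        for i in range(n):
            j = (i + d) % n
            if d == n / 2 and i >= j:
                continue  # antipodal pairs would otherwise appear twice
            rows.append(min(i, j))
            cols.append(max(i, j))
            count += 1
            if count == n_edges:
                return np.array(rows), np.array(cols)
    return np.array(rows), np.array(cols)


def _mean_offdiag(matrix: np.ndarray) -> float:
    n = matrix.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(np.nanmean(matrix[mask]))


def _weighted_from_edges(n, rows, cols, weight_values):
    w = np.zeros((n, n))
    w[rows, cols] = weight_values
    w[cols, rows] = weight_values
    return w


def lattice_reference(n: int, weight_multiset: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One-dimensional ring lattice matched in size/edge count/weights."""
    rows, cols = _ring_lattice_edges(n, len(weight_multiset))
    return _weighted_from_edges(n, rows, cols, rng.permutation(weight_multiset))


def random_reference(n: int, weight_multiset: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform random graph matched in size/edge count/weights."""
    n_pairs = n * (n - 1) // 2
    chosen = rng.choice(n_pairs, size=len(weight_multiset), replace=False)
    iu = np.triu_indices(n, 1)
    rows, cols = iu[0][chosen], iu[1][chosen]
    return _weighted_from_edges(n, rows, cols, rng.permutation(weight_multiset))


def scaled_morphospace(
    weights: np.ndarray, n_realizations: int = 10, seed: int = 0
) -> MorphospacePoint:
    """Standardize mean SPE and mean CMY against lattice/random ensembles.

    Each reference realization carries a random permutation of the input's
    weight multiset over a ring-lattice or uniform-random support with the
    same node and edge count.
    """
    w = _validate(weights)
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    multiset = w[iu][w[iu] > 0]
    if len(multiset) == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)

    mean_spe = _mean_offdiag(shortest_path_efficiency(w))
    mean_cmy = _mean_offdiag(communicability(w))

    latt_spe, latt_cmy, rand_spe, rand_cmy = [], [], [], []
    for _ in range(n_realizations):
        latt = lattice_reference(n, multiset, rng)
        rnd = random_reference(n, multiset, rng)
        latt_spe.append(_mean_offdiag(shortest_path_efficiency(latt)))
        latt_cmy.append(_mean_offdiag(communicability(latt)))
        rand_spe.append(_mean_offdiag(shortest_path_efficiency(rnd)))
        rand_cmy.append(_mean_offdiag(communicability(rnd)))
    ref = dict(
        ref_spe_latt=float(np.mean(latt_spe)),
        ref_spe_rand=float(np.mean(rand_spe)),
        ref_cmy_latt=float(np.mean(latt_cmy)),
        ref_cmy_rand=float(np.mean(rand_cmy)),
    )
    if np.isclose(ref["ref_spe_rand"], ref["ref_spe_latt"]) or np.isclose(
        ref["ref_cmy_rand"], ref["ref_cmy_latt"]
    ):
        raise ValueError("degenerate reference ensembles: lattice and random means coincide")
    return MorphospacePoint(
        spe_scaled=(mean_spe - ref["ref_spe_latt"]) / (ref["ref_spe_rand"] - ref["ref_spe_latt"]),
        cmy_scaled=(mean_cmy - ref["ref_cmy_latt"]) / (ref["ref_cmy_rand"] - ref["ref_cmy_latt"]),
        mean_spe=mean_spe,
        mean_cmy=mean_cmy,
        n_realizations=n_realizations,
        **ref,
    )
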