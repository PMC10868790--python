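"""Core container for one animal's connectome.

A :class:`ConnectomeBundle` carries everything the downstream analyses need
for a single animal: the weighted structural-connectivity matrix, node
coordinates, hemisphere labels, a sparse fiber-length matrix defined on the
connectivity support, and metadata (species, taxonomic order, brain / grey
matter / white matter volumes). Synthetic bundles additionally carry the
planted module partition used as ground truth in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

__all__ = ["ConnectomeBundle", "BundleValidationError", "euclidean_distance_matrix"]


class BundleValidationError(ValueError):
    """Raised when a bundle violates its structural invariants."""


def euclidean_distance_matrix(coordinates: np.ndarray) -> np.ndarray:
    """Pairwise straight-line (Euclidean) distances between node centroids."""
    coords = np.asarray(coordinates, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class ConnectomeBundle:
    """One animal's weighted network, geometry and volumes.

    Parameters
    ----------
    weights
        N x N symmetric non-negative connectivity matrix (streamline-count
        derived, unitless), zero diagonal.
    coordinates
        N x 3 node centroid coordinates in voxel units.
    hemisphere
        Length-N array of ``"L"`` / ``"R"`` labels.
    fiber_length
        Sparse N x N symmetric matrix of tract lengths, defined only where
        ``weights > 0`` (same units as Euclidean distance).
    metadata
        Free-form dict; canonical keys are ``animal_id``, ``species``,
        ``order``, ``brain_volume``, ``gm_volume``, ``wm_volume``,
        ``volume_unit``.
    planted_partition
        Optional ground-truth module labels (synthetic cohorts only).
    """

    weights: np.ndarray
    coordinates: np.ndarray
    hemisphere: np.ndarray
    fiber_length: sp.spmatrix
    metadata: dict = field(default_factory=dict)
    planted_partition: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere)
        if not sp.issparse(self.fiber_length):
            self.fiber_length = sp.csr_matrix(np.asarray(self.fiber_length, dtype=float))
        else:
            self.fiber_length = self.fiber_length.tocsr()
        if self.planted_partition is not None:
            self.planted_partition = np.asarray(self.planted_partition, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def euclidean_distances(self) -> np.ndarray:
        return euclidean_distance_matrix(self.coordinates)

    def density(self) -> float:
        n = self.n_nodes
        n_edges = int(np.count_nonzero(np.triu(self.weights, 1)))
        return n_edges / (n * (n - 1) / 2)

    def cost_matrix(self) -> np.ndarray:
        """Connection cost: edge weight times tract length (0 off-support)."""
        return self.weights * self.fiber_length.toarray()

    def validate(self) -> None:
        """Check all structural invariants; raise listing offending fields."""
        problems = []
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            problems.append("weights must be a square matrix")
        else:
            n = w.shape[0]
            if not np.allclose(w, w.T):
                problems.append("weights symmetry violated")
            if np.any(np.diag(w) != 0):
                problems.append("weights diagonal must be zero")
            if np.any(w < 0):
                problems.append("weights must be non-negative")
            if self.coordinates.shape != (n, 3):
                problems.append(
                    f"coordinates shape {self.coordinates.shape} does not match {n} nodes x 3"
                )
            if self.hemisphere.shape != (n,):
                problems.append("hemisphere labels must be one per node")
            elif not set(np.unique(self.hemisphere)) <= {"L", "R"}:
                problems.append("hemisphere labels must be 'L' or 'R'")
            fl = self.fiber_length
            if fl.shape != (n, n):
                problems.append("fiber_length shape mismatch")
            else:
                fl_dense = fl.toarray()
                if not np.allclose(fl_dense, fl_dense.T):
                    problems.append("fiber_length symmetry violated")
                if np.any((fl_dense != 0) & (w == 0)):
                    problems.append("fiber_length defined where weights are zero")
            if self.planted_partition is not None and self.planted_partition.shape != (n,):
                problems.append("planted_partition must be one label per node")
        if problems:
            raise BundleValidationError("; ".join(problems))
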