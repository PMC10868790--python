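"""Synthetic cohort generator.

Emulates the statistical structure of a cross-species connectome cohort:
brain volumes spanning more than four orders of magnitude, grey- and
white-matter volumes obeying configurable log10-space power laws, and
spatially embedded modular networks whose distance penalty tightens with
brain volume, so that larger "brains" have spatially more compact, denser
modules — the planted trend the downstream statistics are asked to recover.

Geometry is built in normalized units (hemisphere point clouds of unit
scale) and then scaled by ``volume ** (1/3)``; edge probabilities and
weights use the normalized distances, so network density is comparable
across volumes while stored coordinates grow with brain size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .bundle import ConnectomeBundle

__all__ = ["CohortSpec", "generate_volume_table", "generate_connectome", "generate_cohort"]

#: Taxonomic-order stand-in labels, ordered from small to large mean volume.
ORDER_LABELS = [
    "Eulipotyphla", "Chiroptera", "Rodentia", "Lagomorpha", "Cingulata",
    "Marsupialia", "Afrotheria", "Eutheria", "Carnivora", "Primates",
    "Artiodactyla", "Perissodactyla",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Volumes are in cm^3 for ``volume_range`` (converted to mm^3 internally,
    the unit the power laws are calibrated in). The power laws are
    ``log10 GM = gm_slope * log10 BV + gm_intercept`` and
    ``log10 WM = wm_slope * log10 GM + wm_intercept``, with additive
    Gaussian noise of sd ``noise_sd`` in log10 space.

    ``spatial_decay_base`` is the edge-probability decay length in units of
    the hemisphere cloud radius; ``spatial_decay_volume_coupling`` shrinks
    it with log-volume, planting the volume trends.
    """

    n_animals: int = 200
    n_nodes: int = 200
    volume_range: Tuple[float, float] = (0.0842, 1597.3)  # cm^3
    gm_slope: float = 0.98
    gm_intercept: float = 0.013
    wm_slope: float = 1.16
    wm_intercept: float = -1.45
    noise_sd: float = 0.05
    n_modules: int = 4  # per hemisphere
    spatial_decay_base: float = 1.0
    spatial_decay_volume_coupling: float = 0.2
    within_module_boost: float = 4.0
    weight_noise_sd: float = 1.0  # lognormal sd (natural-log space) of edge weights
    target_density: float = 0.15
    fiber_length_factor: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes % 2 != 0 or self.n_nodes < 4:
            raise ValueError("n_nodes must be even and >= 4")
        lo, hi = self.volume_range
        if not (0 < lo < hi):
            raise ValueError("volume_range must be positive and ordered")
        if not (0 < self.target_density <= 1):
            raise ValueError("target_density must be in (0, 1]")
        if self.n_modules < 2:
            raise ValueError("n_modules must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.fiber_length_factor < 1.0:
            raise ValueError("fiber_length_factor must be >= 1 (tracts are not shorter than straight lines)")


def _animal_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    # one independent stream per animal so cohorts are order-independent
    return np.random.default_rng(np.random.SeedSequence((spec.seed, index)))


def generate_volume_table(spec: CohortSpec) -> pd.DataFrame:
    """Sample per-animal brain / GM / WM volumes obeying the power laws.

    Brain volume is log-uniform over ``spec.volume_range``; GM follows the
    GM–BV law and WM the WM–GM law, each with lognormal multiplicative
    noise. Returns a DataFrame with columns ``animal_id``, ``order``,
    ``brain_volume``, ``gm_volume``, ``wm_volume`` (mm^3) and a
    ``volume_unit`` column recording the unit.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x5F0A11)))
    lo, hi = (v * 1000.0 for v in spec.volume_range)  # cm^3 -> mm^3
    log_bv = rng.uniform(np.log10(lo), np.log10(hi), size=spec.n_animals)
    log_gm = spec.gm_slope * log_bv + spec.gm_intercept + rng.normal(0, spec.noise_sd, spec.n_animals)
    log_wm = spec.wm_slope * log_gm + spec.wm_intercept + rng.normal(0, spec.noise_sd, spec.n_animals)

    # pseudo-taxonomic orders: volume-ordered groups, echoing the observed
    # collinearity between order and brain volume
    order_idx = np.minimum(
        (np.argsort(np.argsort(log_bv)) * len(ORDER_LABELS)) // spec.n_animals,
        len(ORDER_LABELS) - 1,
    )
    return pd.DataFrame(
        {
            "animal_id": [f"animal_{i:03d}" for i in range(spec.n_animals)],
            "order": [ORDER_LABELS[i] for i in order_idx],
            "brain_volume": 10.0**log_bv,
            "gm_volume": 10.0**log_gm,
            "wm_volume": 10.0**log_wm,
            "volume_unit": "mm3",
        }
    )


def _hemisphere_cloud(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform points in a unit ball centered at x = -1.2 (left hemisphere)."""
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= rng.uniform(0, 1, size=(n, 1)) ** (1 / 3)
    pts[:, 0] -= 1.2
    return pts


def _decay_length(volume_cm3: float, spec: CohortSpec) -> float:
    """Distance-penalty length scale; shrinks geometrically with log-volume.

    Each decade of brain volume multiplies the decay length by
    ``10**(-spatial_decay_volume_coupling)``, so the planted spatial
    tightening is spread evenly across the whole volume range.
    """
    lo = spec.volume_range[0]
    rel = max(np.log10(volume_cm3 / lo), 0.0)
    return spec.spatial_decay_base * 10.0 ** (-spec.spatial_decay_volume_coupling * rel)


def generate_connectome(
    volume: float,
    spec: CohortSpec,
    seed: int,
    *,
    metadata: dict | None = None,
    max_retries: int = 10,
) -> ConnectomeBundle:
    """Generate one spatially embedded modular connectome.

    ``volume`` is the brain volume in cm^3. Nodes are split into two
    mirrored hemispheric clouds; each hemisphere holds ``spec.n_modules``
    spatial module centers, and nodes adopt the nearest center's module.
    Edges appear with probability proportional to
    ``exp(-d_ij / lambda(volume)) * (1 + within_module_boost * same_module)``,
    rescaled to hit ``target_density``; weights decay with distance with
    lognormal jitter. Fiber lengths on existing edges are a supra-Euclidean
    multiple of the straight-line distance.
    """
    spec.validate()
    if volume <= 0:
        raise ValueError("volume must be positive")
    n = spec.n_nodes
    half = n // 2
    rng = np.random.default_rng(np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 17)))

    for attempt in range(max_retries):
        left = _hemisphere_cloud(rng, half)
        right = left.copy()
        right[:, 0] *= -1  # mirror across x = 0
        coords_norm = np.vstack([left, right])

        centers_left = _hemisphere_cloud(rng, spec.n_modules)
        centers_right = centers_left.copy()
        centers_right[:, 0] *= -1
        centers = np.vstack([centers_left, centers_right])
        # soft spatial assignment, hemisphere-restricted so module ids are
        # distinct per hemisphere; the assignment temperature is the same
        # volume-coupled decay length, so module spatial compactness
        # tightens with brain volume (mixed modules in small brains,
        # near-nearest-center modules in large ones)
        lam = _decay_length(volume, spec)
        d_left = np.linalg.norm(left[:, None] - centers_left[None], axis=-1)
        d_right = np.linalg.norm(right[:, None] - centers_right[None], axis=-1)

        def _soft_assign(d_to_centers: np.ndarray) -> np.ndarray:
            logits = -d_to_centers / lam
            p = np.exp(logits - logits.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            cum = np.cumsum(p, axis=1)
            u = rng.uniform(size=(p.shape[0], 1))
            return (u > cum).sum(axis=1)

        partition = np.concatenate(
            [_soft_assign(d_left), _soft_assign(d_right) + spec.n_modules]
        )

        diff = coords_norm[:, None, :] - coords_norm[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        same = partition[:, None] == partition[None, :]
        affinity = np.exp(-dist / lam) * (1.0 + spec.within_module_boost * same)
        iu = np.triu_indices(n, 1)
        raw = affinity[iu]
        # calibrate the global scale so that mean(min(c*raw, 1)) hits the
        # target density even when short-range probabilities saturate at 1
        target = spec.target_density * len(raw)
        c_lo, c_hi = 0.0, 1.0 / raw.max()
        while np.minimum(c_hi * raw, 1.0).sum() < target and c_hi < 1e12:
            c_hi *= 2.0
        for _ in range(60):
            c_mid = 0.5 * (c_lo + c_hi)
            if np.minimum(c_mid * raw, 1.0).sum() < target:
                c_lo = c_mid
            else:
                c_hi = c_mid
        probs = np.minimum(c_hi * raw, 1.0)
        present = rng.uniform(size=len(probs)) < probs

        weights = np.zeros((n, n))
        jitter = rng.lognormal(mean=0.0, sigma=spec.weight_noise_sd, size=present.sum())
        w_vals = np.exp(-dist[iu][present] / lam) * jitter
        rows, cols = iu[0][present], iu[1][present]
        weights[rows, cols] = w_vals
        weights[cols, rows] = w_vals

        n_comp, _ = connected_components(sp.csr_matrix(weights), directed=False)
        if n_comp == 1:
            break
    else:
        raise RuntimeError(
            f"could not generate a connected network in {max_retries} attempts "
            f"(volume={volume}, target_density={spec.target_density})"
        )

    scale = volume ** (1.0 / 3.0)
    coords = coords_norm * scale
    ed_edges = dist[rows, cols] * scale
    fiber = sp.csr_matrix(
        (np.concatenate([ed_edges, ed_edges]) * spec.fiber_length_factor,
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    hemisphere = np.array(["L"] * half + ["R"] * half)
    meta = dict(metadata or {})
    meta.setdefault("brain_volume", volume * 1000.0)
    meta.setdefault("volume_unit", "mm3")
    bundle = ConnectomeBundle(
        weights=weights,
        coordinates=coords,
        hemisphere=hemisphere,
        fiber_length=fiber,
        metadata=meta,
        planted_partition=partition,
    )
    bundle.validate()
    return bundle


def generate_cohort(spec: CohortSpec) -> Tuple[List[ConnectomeBundle], pd.DataFrame]:
    """Generate a full cohort: one bundle per volume-table row.

    Deterministic under ``spec.seed``: each animal derives its own random
    stream from (cohort seed, animal index).
    """
    table = generate_volume_table(spec)
    bundles = []
    for i, row in table.iterrows():
        rng = _animal_rng(spec, i)
        animal_seed = int(rng.integers(0, 2**31 - 1))
        meta = {
            "animal_id": row["animal_id"],
            "species": f"synthetic_sp_{i:03d}",
            "order": row["order"],
            "brain_volume": row["brain_volume"],
            "gm_volume": row["gm_volume"],
            "wm_volume": row["wm_volume"],
            "volume_unit": "mm3",
        }
        bundles.append(
            generate_connectome(
                row["brain_volume"] / 1000.0, spec, animal_seed, metadata=meta
            )
        )
    return bundles, table


def jittered_replicates(
    bundle: ConnectomeBundle, n_replicates: int, seed: int, *, sigma: float = 0.1
) -> List[np.ndarray]:
    """Weight-jittered copies of a bundle's matrix.

    Stands in for the within-animal variability of repeated parcellation
    runs when testing representative-network selection; each replicate
    multiplies existing edge weights by lognormal noise (support unchanged).
    """
    rng = np.random.default_rng(seed)
    out = []
    iu = np.triu_indices(bundle.n_nodes, 1)
    for _ in range(n_replicates):
        w = bundle.weights.copy()
        factor = rng.lognormal(0.0, sigma, size=len(iu[0]))
        vals = w[iu] * factor
        w[iu] = vals
        w[(iu[1], iu[0])] = vals
        out.append(w)
    return out
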