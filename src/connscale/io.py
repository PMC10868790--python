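"""Read/write connectome bundles and cohort manifests.

On-disk layout of a bundle directory::

    <bundle>/
      weights.mtx         # MatrixMarket sparse, symmetric support stored fully
      fiber_length.mtx    # MatrixMarket sparse, support subset of weights
      nodes.csv           # node_id, x, y, z, hemisphere [, planted_module]
      metadata.json       # animal id, species, order, volumes, unit

A cohort manifest is a JSON file with an ordered list of bundle paths
(relative to the manifest) plus a per-animal metadata echo.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, List

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .bundle import BundleValidationError, ConnectomeBundle

__all__ = [
    "write_bundle",
    "read_bundle",
    "write_cohort",
    "read_manifest",
    "iter_cohort",
    "fetch_instructions",
]

_MTX_PRECISION = 17  # full float64 round-trip


def write_bundle(bundle: ConnectomeBundle, path: str | Path) -> Path:
    """Write a validated bundle to a directory; returns the directory path."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(path / "weights.mtx", sp.coo_matrix(bundle.weights), precision=_MTX_PRECISION)
    mmwrite(path / "fiber_length.mtx", sp.coo_matrix(bundle.fiber_length), precision=_MTX_PRECISION)
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(bundle.n_nodes),
            "x": bundle.coordinates[:, 0],
            "y": bundle.coordinates[:, 1],
            "z": bundle.coordinates[:, 2],
            "hemisphere": bundle.hemisphere,
        }
    )
    if bundle.planted_partition is not None:
        nodes["planted_module"] = bundle.planted_partition
    nodes.to_csv(path / "nodes.csv", index=False, float_format="%.17g")
    with open(path / "metadata.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True, default=float)
    return path


def read_bundle(path: str | Path) -> ConnectomeBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    for name in ("weights.mtx", "fiber_length.mtx", "nodes.csv", "metadata.json"):
        if not (path / name).exists():
            raise FileNotFoundError(f"bundle component missing: {path / name}")
    weights_raw = mmread(path / "weights.mtx")
    weights = np.asarray(weights_raw.todense()) if sp.issparse(weights_raw) else np.asarray(weights_raw)
    fiber = sp.csr_matrix(mmread(path / "fiber_length.mtx"))
    nodes = pd.read_csv(path / "nodes.csv", float_precision="round_trip")
    n = weights.shape[0]
    if len(nodes) != n:
        raise BundleValidationError(
            f"nodes.csv has {len(nodes)} rows but weights matrix is {n}x{n}"
        )
    with open(path / "metadata.json") as fh:
        metadata = json.load(fh)
    planted = nodes["planted_module"].to_numpy() if "planted_module" in nodes else None
    bundle = ConnectomeBundle(
        weights=weights,
        coordinates=nodes[["x", "y", "z"]].to_numpy(),
        hemisphere=nodes["hemisphere"].to_numpy(),
        fiber_length=fiber,
        metadata=metadata,
        planted_partition=planted,
    )
    bundle.validate()
    return bundle


def write_cohort(
    bundles: List[ConnectomeBundle], directory: str | Path, manifest_name: str = "cohort.json"
) -> Path:
    """Write a cohort of bundles plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    seen = set()
    for bundle in bundles:
        animal_id = bundle.metadata.get("animal_id", f"animal_{len(entries):03d}")
        if animal_id in seen:
            raise ValueError(f"duplicate animal_id in cohort: {animal_id}")
        seen.add(animal_id)
        write_bundle(bundle, directory / animal_id)
        entries.append({"path": animal_id, "metadata": bundle.metadata})
    manifest = directory / manifest_name
    with open(manifest, "w") as fh:
        json.dump({"bundles": entries}, fh, indent=2, sort_keys=True, default=float)
    return manifest


def read_manifest(manifest_path: str | Path) -> List[Path]:
    """Resolve a manifest to its ordered bundle paths (checked to exist)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    paths = [manifest_path.parent / entry["path"] for entry in manifest["bundles"]]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing bundles: {missing}")
    return paths


def iter_cohort(manifest_path: str | Path) -> Iterator[ConnectomeBundle]:
    """Yield bundles in manifest order."""
    for path in read_manifest(manifest_path):
        yield read_bundle(path)


def fetch_instructions() -> str:
    """How to obtain the deposited cross-species dataset (manual download).

    The cross-species mammalian connectome deposit lives on Zenodo under DOI
    10.5281/zenodo.10372945. This package does not download it (analyses
    run offline on synthetic cohorts); to use the real data, download and
    unpack the archive, then adapt its matrices into bundle directories via
    :class:`~connscale.bundle.ConnectomeBundle` and :func:`write_bundle`.
    """
    return (
        "Download https://doi.org/10.5281/zenodo.10372945, unpack, and convert "
        "each animal's weight/length matrices and coordinates into a bundle "
        "directory with connscale.io.write_bundle."
    )
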