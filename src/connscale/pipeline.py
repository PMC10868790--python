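"""Cohort-level orchestration.

Per animal: optional density thresholding, the multiresolution consensus
sweep, co-classification matrix and consensus partition, module features,
communication matrices, morphospace coordinates, and the node-pair
couplings. Across animals: Fisher-z-transformed couplings and module
features are rank-correlated with brain volume, and the GM/WM/BV scaling
laws are fit with the subsampling bootstrap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import communication, modularity, stats
from .bundle import ConnectomeBundle
from .density import threshold_to_density
from .io import iter_cohort

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "analyze_bundle", "run_cohort_analysis", "summarize_results"]

#: coupling columns that are Fisher z-transformed before the volume panel
COUPLING_COLUMNS = [
    "rho_cc_weight",
    "rho_cc_cost",
    "rho_cc_ed",
    "rho_ed_spe",
    "rho_ed_nsi",
    "rho_ed_cmy",
    "rho_cc_spe",
    "rho_cc_nsi",
    "rho_cc_cmy",
]

#: plain feature columns entering the volume panel untransformed
FEATURE_COLUMNS = ["imd", "longdist_fraction", "interhemispheric_cc", "spe_scaled", "cmy_scaled"]


@dataclass
class AnalysisConfig:
    """Serializable knobs that, with the cohort, fully determine a run."""

    density: Optional[float] = None  # None = unthresholded
    n_gamma: int = 100  # per MRCC step; 500 for full-scale runs
    gamma_range: Tuple[float, float] = (0.01, 10.0)
    consensus_restarts: int = 100
    morphospace_realizations: int = 10
    n_boot: int = 10_000
    bootstrap_frac: float = 0.9
    seed: int = 0
    max_failure_fraction: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def analyze_bundle(bundle: ConnectomeBundle, config: AnalysisConfig, seed: int) -> dict:
    """Compute one animal's feature row."""
    weights = bundle.weights
    if config.density is not None:
        weights = threshold_to_density(weights, config.density)
    ed = bundle.euclidean_distances()
    cost = weights * bundle.fiber_length.toarray()

    ensemble = modularity.mrcc_ensemble(
        weights, n_gamma=config.n_gamma, coarse_range=config.gamma_range, seed=seed
    )
    cc = modularity.coclassification_matrix(ensemble)
    consensus = modularity.consensus_from_cc(cc, seed=seed, n_restarts=config.consensus_restarts)
    features = modularity.partition_features(weights, ed, consensus)
    inter_cc = modularity.interhemispheric_cc(cc, bundle.hemisphere)

    comm = communication.communication_set(weights)
    morpho = communication.scaled_morphospace(
        weights, n_realizations=config.morphospace_realizations, seed=seed
    )

    valid = comm.valid
    row = {
        "animal_id": bundle.metadata.get("animal_id", ""),
        "order": bundle.metadata.get("order", ""),
        "brain_volume": bundle.metadata.get("brain_volume", np.nan),
        "gm_volume": bundle.metadata.get("gm_volume", np.nan),
        "wm_volume": bundle.metadata.get("wm_volume", np.nan),
        "rho_cc_weight": stats.pairwise_coupling(cc, weights),
        "rho_cc_cost": stats.pairwise_coupling(cc, cost),
        "rho_cc_ed": stats.pairwise_coupling(cc, ed),
        "rho_ed_spe": stats.pairwise_coupling(ed, comm.spe, valid),
        "rho_ed_nsi": stats.pairwise_coupling(ed, comm.nsi, valid),
        "rho_ed_cmy": stats.pairwise_coupling(ed, comm.cmy, valid),
        "rho_cc_spe": stats.pairwise_coupling(cc, comm.spe, valid),
        "rho_cc_nsi": stats.pairwise_coupling(cc, comm.nsi, valid),
        "rho_cc_cmy": stats.pairwise_coupling(cc, comm.cmy, valid),
        "imd": features["imd"],
        "longdist_fraction": features["longdist_fraction"],
        "interhemispheric_cc": inter_cc,
        "spe_scaled": morpho.spe_scaled,
        "cmy_scaled": morpho.cmy_scaled,
        "n_modules_consensus": consensus.n_modules,
        "q_consensus": consensus.q,
        "ensemble_size": len(ensemble),
        "gamma_low": ensemble.gamma_low,
        "gamma_high": ensemble.gamma_high,
    }
    return row


def volume_panel(features: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each feature with brain volume.

    Coupling columns are Fisher z-transformed first (rank statistics are
    invariant to this monotone transform; kept for scale reporting).
    """
    rows = []
    vol = features["brain_volume"].to_numpy(dtype=float)
    for col in COUPLING_COLUMNS + FEATURE_COLUMNS:
        if col not in features:
            continue
        vals = features[col].to_numpy(dtype=float)
        if col in COUPLING_COLUMNS:
            vals = stats.fisher_z(vals)
        ok = np.isfinite(vals) & np.isfinite(vol)
        if ok.sum() < 3:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.rank_correlation(vol[ok], vals[ok])
        rows.append({"feature": col, "rho": rho, "p_value": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def scaling_fits(features: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Bootstrap WM~GM and GM~BV power-law fits from the cohort volumes."""
    out = {}
    pairs = {
        "wm_vs_gm": ("gm_volume", "wm_volume"),
        "gm_vs_bv": ("brain_volume", "gm_volume"),
    }
    for name, (xcol, ycol) in pairs.items():
        x = features[xcol].to_numpy(dtype=float)
        y = features[ycol].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
        try:
            out[name] = stats.bootstrap_loglog_fit(
                x[ok], y[ok], frac=config.bootstrap_frac, n_boot=config.n_boot, seed=config.seed
            )
        except ValueError as exc:  # too few usable animals for a fit
            logger.warning("scaling fit %s unavailable: %s", name, exc)
            out[name] = None
    return out


def run_cohort_analysis(
    cohort: Sequence[ConnectomeBundle] | str,
    config: AnalysisConfig | None = None,
    covariate_column: Optional[str] = None,
) -> dict:
    """Run the full per-animal + cross-animal analysis.

    ``cohort`` is a list of bundles or a manifest path. Per-animal failures
    are isolated and logged; the run fails only if the failed fraction
    exceeds ``config.max_failure_fraction``. Returns a dict with keys
    ``features`` (per-animal DataFrame), ``panel`` (volume-correlation
    DataFrame), ``fits`` (scaling-law fits), ``failures`` and, when a
    covariate column is named, ``partial_panel``.
    """
    config = config or AnalysisConfig()
    bundles = list(iter_cohort(cohort)) if isinstance(cohort, (str,)) else list(cohort)
    rows, failures = [], []
    for i, bundle in enumerate(bundles):
        try:
            rows.append(analyze_bundle(bundle, config, seed=config.seed * 100_003 + i))
        except Exception as exc:  # noqa: BLE001 - failures are isolated by contract
            animal = bundle.metadata.get("animal_id", f"index_{i}")
            logger.warning("animal %s failed: %s", animal, exc)
            failures.append({"animal_id": animal, "error": str(exc)})
    if bundles and len(failures) / len(bundles) > config.max_failure_fraction:
        raise RuntimeError(
            f"{len(failures)}/{len(bundles)} animals failed, above the configured tolerance; "
            f"first error: {failures[0]['error']}"
        )
    features = pd.DataFrame(rows)
    result = {
        "features": features,
        "panel": volume_panel(features),
        "fits": scaling_fits(features, config),
        "failures": failures,
        "config": config,
    }
    if covariate_column is not None:
        result["partial_panel"] = _partial_panel(features, covariate_column)
    return result


def _partial_panel(features: pd.DataFrame, covariate_column: str) -> pd.DataFrame:
    cov = features[covariate_column]
    cov_mat = stats.one_hot(cov) if cov.dtype == object else cov.to_numpy(dtype=float)[:, None]
    vol = features["brain_volume"].to_numpy(dtype=float)
    rows = []
    for col in COUPLING_COLUMNS + FEATURE_COLUMNS:
        if col not in features:
            continue
        vals = features[col].to_numpy(dtype=float)
        if col in COUPLING_COLUMNS:
            vals = stats.fisher_z(vals)
        ok = np.isfinite(vals) & np.isfinite(vol)
        if ok.sum() < 4:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.partial_rank_correlation(vol[ok], vals[ok], cov_mat[ok])
        rows.append({"feature": col, "rho_partial": rho, "p_value": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def summarize_results(result: dict) -> str:
    """Human-readable report of scaling fits and the correlation panel."""
    features = result["features"]
    if features.empty:
        raise ValueError("empty feature table")
    lines = ["Cohort analysis summary", "=" * 23, ""]
    lines.append(f"Animals analyzed: {len(features)} (failures: {len(result.get('failures', []))})")
    lines.append("")
    lines.append("Scaling laws (log10 space, subsampling bootstrap):")
    for name, fit in result["fits"].items():
        if fit is None:
            lines.append(f"  {name}: unavailable (too few usable animals)")
            continue
        lines.append(
            f"  {name}: slope {fit.slope_mean:.4f} +/- {fit.slope_sd:.4f}, "
            f"intercept {fit.intercept_mean:.4f} +/- {fit.intercept_sd:.4f} "
            f"(n_boot={fit.n_boot})"
        )
    lines.append("")
    lines.append("Feature vs brain-volume Spearman panel:")
    for _, row in result["panel"].iterrows():
        lines.append(
            f"  {row['feature']:<22} rho = {row['rho']:+.3f}  p = {row['p_value']:.3g}  (n={row['n']})"
        )
    if "partial_panel" in result:
        lines.append("")
        lines.append("Partial rank correlations (covariate-controlled):")
        for _, row in result["partial_panel"].iterrows():
            lines.append(
                f"  {row['feature']:<22} rho = {row['rho_partial']:+.3f}  p = {row['p_value']:.3g}"
            )
    return "\n".join(lines)
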