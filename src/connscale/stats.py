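"""Cross-animal statistics.

Bootstrapped log-log power-law fits, Spearman rank correlations, a
rank-based partial correlation for covariate control, and the pairwise
coupling between node-pair matrices (e.g. co-classification probability vs
Euclidean distance) that produces the per-animal scalar features. Per-animal
correlation coefficients are Fisher z-transformed (atanh) before the
cross-animal correlation — a variance-stabilizing monotone transform that
leaves rank-based statistics unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "ScalingFit",
    "pairwise_coupling",
    "bootstrap_loglog_fit",
    "rank_correlation",
    "partial_rank_correlation",
    "fisher_z",
]

#: atanh clip bound, avoids infinities on degenerate (|rho| = 1) toys
_ATANH_CLIP = 1.0 - 1e-12


@dataclass
class ScalingFit:
    """Bootstrap summary of a log10-space linear (power-law) fit."""

    slope_mean: float
    slope_sd: float
    intercept_mean: float
    intercept_sd: float
    n_boot: int
    frac: float
    seed: int


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing atanh transform, clipped near |rho| = 1."""
    return np.arctanh(np.clip(rho, -_ATANH_CLIP, _ATANH_CLIP))


def pairwise_coupling(
    a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Spearman correlation between two node-pair matrices.

    Computed over the upper-triangle entries selected by ``mask`` (the
    diagonal is always excluded). Returns NaN if either input is constant
    over the selected pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape")
    n = a.shape[0]
    sel = np.triu(np.ones((n, n), dtype=bool), 1)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    x, y = a[sel], b[sel]
    if len(x) < 3:
        raise ValueError("fewer than 3 valid pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def bootstrap_loglog_fit(
    x: np.ndarray,
    y: np.ndarray,
    frac: float = 0.9,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ScalingFit:
    """Bootstrap a power-law fit of y on x in log10 space.

    Each iteration subsamples ``floor(frac * n)`` observations without
    replacement and fits ordinary least squares of log10 y on log10 x;
    the mean and sd of slope and intercept over iterations are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("x and y must be positive (log undefined otherwise)")
    n = len(x)
    if n < 5 or len(y) != n:
        raise ValueError("need matched x, y with n >= 5")
    lx, ly = np.log10(x), np.log10(y)
    k = int(np.floor(frac * n))
    if k < 2:
        raise ValueError("subsample too small to fit a line")
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    for it in range(n_boot):
        idx = rng.choice(n, size=k, replace=False)
        slope, intercept = np.polyfit(lx[idx], ly[idx], 1)
        slopes[it] = slope
        intercepts[it] = intercept
    return ScalingFit(
        slope_mean=float(slopes.mean()),
        slope_sd=float(slopes.std(ddof=0)),
        intercept_mean=float(intercepts.mean()),
        intercept_sd=float(intercepts.std(ddof=0)),
        n_boot=n_boot,
        frac=frac,
        seed=seed,
    )


def rank_correlation(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Spearman rho with large-sample p-value; ties are midranked.

    Returns (nan, nan) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) != len(x):
        raise ValueError("need matched x, y with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def partial_rank_correlation(
    x: np.ndarray, y: np.ndarray, covariates: Optional[np.ndarray] = None
) -> Tuple[float, float]:
    """Spearman partial correlation of x and y given covariates.

    All variables are rank-transformed; x and y are residualized on the
    covariate ranks (plus intercept) by least squares and the residuals are
    correlated. With no covariates this reduces to the plain Spearman
    correlation. The p-value uses a t statistic with n - 2 - q degrees of
    freedom, q the number of covariate columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and np.asarray(covariates).size == 0):
        return rank_correlation(x, y)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n or len(y) != n:
        raise ValueError("covariates must align with x and y")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rc = np.column_stack([np.ones(n)] + [sps.rankdata(cov[:, j]) for j in range(cov.shape[1])])
    if np.linalg.matrix_rank(rc) < rc.shape[1]:
        raise ValueError("collinear covariates")
    res_x = rx - rc @ np.linalg.lstsq(rc, rx, rcond=None)[0]
    res_y = ry - rc @ np.linalg.lstsq(rc, ry, rcond=None)[0]
    denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    rho = float((res_x * res_y).sum() / denom)
    df = n - 2 - cov.shape[1]
    if df <= 0:
        return rho, float("nan")
    rho_c = np.clip(rho, -_ATANH_CLIP, _ATANH_CLIP)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return rho, p


def one_hot(labels) -> np.ndarray:
    """One-hot encode categorical labels, dropping the first level.

    The reference-level drop keeps the design full rank once an intercept
    is added (the default covariate encoding for taxonomic orders).
    """
    labels = np.asarray(labels)
    levels = np.unique(labels)
    return np.column_stack([(labels == lev).astype(float) for lev in levels[1:]])
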