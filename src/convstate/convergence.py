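"""Convergence-state statistic: leave-one-run-out pattern typicality.

A trial's multivoxel activation pattern is a point in voxel space.  The
prototypical state (centroid) is estimated from all runs except the one
containing the trial, and the trial is scored by its correlation distance
(1 - Pearson's r) from that held-out-fold centroid.  Shorter distance =
higher typicality = greater convergence.

Two centroid estimators are provided:

``kmeans_mean``
    The mean of row-standardized patterns — the closed-form k = 1 k-means
    solution under correlation geometry.  Deterministic; the default.
``medoid``
    The pattern minimizing summed correlation distance to all training
    patterns ("the point with the shortest distance to all other points").

The two coincide for tight clusters but diverge for, e.g., antipodal
pattern sets; both are exposed and tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "correlation_distance",
    "compute_centroid",
    "loro_typicality",
    "zscore_within_subject",
    "flag_outliers",
    "Centroid",
]

logger = logging.getLogger(__name__)

CENTROID_METHODS = ("kmeans_mean", "medoid")


def _check_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 3:
        raise ValueError(f"{name} must have length >= 3, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError(f"{name} has zero variance; correlation distance undefined")
    return v


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson's r between two voxel vectors.

    Symmetric, in [0, 2], and invariant to per-vector additive shifts and
    positive rescaling.  Zero-variance inputs raise rather than silently
    returning 0 or NaN.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)))
    return 1.0 - max(-1.0, min(1.0, r))


def _standardize_rows(patterns: np.ndarray) -> np.ndarray:
    mu = patterns.mean(axis=1, keepdims=True)
    sd = patterns.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd.ravel() == 0).tolist()
        raise ValueError(f"constant pattern rows (zero variance): {bad}")
    return (patterns - mu) / sd


def _distances_to(patterns: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Correlation distance of each row of ``patterns`` from ``centroid``."""
    z = _standardize_rows(np.asarray(patterns, dtype=float))
    c = np.asarray(centroid, dtype=float)
    cc = c - c.mean()
    nc = np.linalg.norm(cc)
    if nc == 0:
        raise ValueError("centroid has zero variance")
    r = (z @ cc) / (np.sqrt(z.shape[1]) * nc)
    return 1.0 - np.clip(r, -1.0, 1.0)


@dataclass
class Centroid:
    vector: np.ndarray
    method: str
    sum_distance: float
    n_source_trials: int

    @property
    def standardized(self) -> np.ndarray:
        c = self.vector - self.vector.mean()
        return c / c.std()


def compute_centroid(patterns: np.ndarray, method: str = "kmeans_mean") -> Centroid:
    """Prototypical-state centroid of a trials x voxels matrix.

    ``kmeans_mean`` returns the mean of row-standardized patterns (the
    single-cluster k-means solution under correlation geometry, closed
    form, no stochastic initialization); ``medoid`` returns the row with
    the smallest summed correlation distance to all rows.  Both report the
    achieved summed distance to the training patterns.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 trial rows")
    if patterns.shape[1] < 3:
        raise ValueError("need at least 3 voxels")
    if method == "kmeans_mean":
        vec = _standardize_rows(patterns).mean(axis=0)
        if np.ptp(vec) == 0:
            raise ValueError(
                "mean centroid is constant; patterns cancel under correlation geometry"
            )
        sum_d = float(_distances_to(patterns, vec).sum())
    elif method == "medoid":
        z = _standardize_rows(patterns)
        nv = patterns.shape[1]
        # pairwise correlation via standardized rows: r_ij = z_i . z_j / nv
        r = (z @ z.T) / nv
        d = 1.0 - np.clip(r, -1.0, 1.0)
        sums = d.sum(axis=1)
        best = int(np.argmin(sums))
        vec = patterns[best].copy()
        sum_d = float(sums[best])
    else:
        raise ValueError(f"unknown centroid method {method!r}; use one of {CENTROID_METHODS}")
    return Centroid(
        vector=vec, method=method, sum_distance=sum_d, n_source_trials=patterns.shape[0]
    )


def loro_typicality(
    patterns: np.ndarray,
    run_labels: np.ndarray,
    method: str = "kmeans_mean",
) -> tuple[pd.DataFrame, dict]:
    """Leave-one-run-out typicality for one subject.

    For each run r the centroid is estimated from all trials with
    run != r, and every trial of run r is scored by its correlation
    distance from that centroid; each trial is scored exactly once.
    Returns a table aligned with the input rows (columns ``run``,
    ``distance``) and the per-fold :class:`Centroid` set.
    """
    patterns = np.asarray(patterns, dtype=float)
    run_labels = np.asarray(run_labels)
    if patterns.shape[0] != run_labels.size:
        raise ValueError("run_labels length must match pattern rows")
    runs = np.unique(run_labels)
    if runs.size < 2:
        raise ValueError("leave-one-run-out needs at least 2 distinct runs")
    distance = np.full(patterns.shape[0], np.nan)
    centroids: dict = {}
    for r in runs:
        test = run_labels == r
        train = ~test
        if train.sum() < 2:
            raise ValueError(f"fewer than 2 training trials when leaving out run {r!r}")
        cen = compute_centroid(patterns[train], method=method)
        centroids[r] = cen
        distance[test] = _distances_to(patterns[test], cen.vector)
    table = pd.DataFrame({"run": run_labels, "distance": distance})
    return table, centroids


def zscore_within_subject(
    table: pd.DataFrame,
    group_cols: list[str] | str = "subject_id",
    value_col: str = "distance",
    out_col: str = "z_distance",
) -> pd.DataFrame:
    """Standardize distances across trials within each subject.

    Adds ``out_col`` = (d - mean) / sd per group (sd with ddof = 1); the
    raw distances are retained, since downstream models use the raw score.
    """
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    out = table.copy()
    grouped = out.groupby(group_cols, sort=False)[value_col]
    counts = grouped.transform("count")
    if (counts < 2).any():
        raise ValueError("each subject needs at least 2 trials to standardize")
    mu = grouped.transform("mean")
    sd = grouped.transform("std")
    if (sd == 0).any():
        bad = out.loc[sd == 0, group_cols].drop_duplicates().to_dict("records")
        raise ValueError(f"zero within-subject variance for {bad}")
    out[out_col] = (out[value_col] - mu) / sd
    return out


def flag_outliers(
    table: pd.DataFrame, threshold_sd: float = 3.0, z_col: str = "z_distance"
) -> pd.DataFrame:
    """Flag trials whose standardized distance exceeds ``threshold_sd``.

    Adds a binary ``outlier_flag`` column; downstream models accept an
    include/exclude switch.  The flagged fraction is logged.
    """
    if z_col not in table.columns:
        raise ValueError(f"column {z_col!r} not present; run zscore_within_subject first")
    out = table.copy()
    out["outlier_flag"] = (out[z_col].abs() > threshold_sd).astype(int)
    frac = float(out["outlier_flag"].mean())
    logger.info("flagged %.3f%% of trials as outliers (>%g SD)", 100 * frac, threshold_sd)
    return out
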