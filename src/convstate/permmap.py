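"""Permutation-null-adjusted voxelwise correlation maps.

For each subject, hippocampal pattern typicality is correlated with every
voxel's univariate activation after residualizing both on a covariate
(the VTA signal).  A per-voxel null distribution is built from
within-subject permutations of the typicality vector's trial order — the
minimal exchangeable null for a trialwise correlation — and the null
r-value at the 95th percentile is subtracted from the observed r, so only
correlations exceeding their own null quantile stay positive.  A group
one-sample t-test over subjects then identifies voxels with reliable
coupling, with family-wise error control by Bonferroni (default) or a
max-statistic sign-flip permutation test.

Permutations are shared across voxels within a subject (vectorized and
variance-reducing), and the covariate residualization is applied
identically in the observed and permuted computations so the null matches
the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "residualize",
    "voxelwise_r",
    "null_adjust",
    "group_test",
    "BrainMapResult",
]

logger = logging.getLogger(__name__)


def residualize(y: np.ndarray, covariate: np.ndarray | None) -> np.ndarray:
    """Residuals of y regressed on covariate + intercept (mean 0, orthogonal
    to the covariate).  With no covariate this is plain centering."""
    y = np.asarray(y, dtype=float)
    if covariate is None:
        return y - y.mean(axis=0)
    c = np.asarray(covariate, dtype=float).ravel()
    if np.ptp(c) == 0:
        raise ValueError("constant covariate; residualization undefined")
    if len(c) != len(y):
        raise ValueError("covariate length must match y")
    cc = c - c.mean()
    yc = y - y.mean(axis=0)
    slope = (cc @ yc) / (cc @ cc)
    return yc - np.outer(cc, slope) if yc.ndim == 2 else yc - slope * cc


def _corr_rows_with_matrix(t_rows: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pearson r between each centered row of t_rows (k, n) and each centered
    column of V (n, v) -> (k, v).  Zero-variance columns give NaN."""
    tn = np.linalg.norm(t_rows, axis=1, keepdims=True)
    vn = np.linalg.norm(V, axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (t_rows @ V) / (tn * vn)
    r[:, vn.ravel() == 0] = np.nan
    return r


def voxelwise_r(
    typicality: np.ndarray,
    voxels: np.ndarray,
    covariate: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel Pearson r between residualized typicality and each
    residualized voxel series (one subject).  Zero-variance voxels are
    recorded as NaN and logged."""
    typicality = np.asarray(typicality, dtype=float).ravel()
    voxels = np.asarray(voxels, dtype=float)
    if voxels.ndim != 2 or voxels.shape[0] != typicality.size:
        raise ValueError("voxels must be (n_trials x n_voxels) matching typicality")
    if typicality.size < 4:
        raise ValueError("need at least 4 trials")
    t_res = residualize(typicality, covariate)
    v_res = residualize(voxels, covariate)
    r = _corr_rows_with_matrix(t_res[None, :], v_res)[0]
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        logger.info("%d zero-variance voxel(s); r recorded as missing", n_bad)
    return r


def null_adjust(
    r_obs: np.ndarray,
    typicality: np.ndarray,
    voxels: np.ndarray,
    covariate: np.ndarray | None,
    n_perm: int = 500,
    alpha_percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Subtract each voxel's permutation-null quantile from its observed r.

    The null permutes the raw typicality vector's trial order within
    subject (n_perm draws, shared across voxels), residualizes exactly as
    the observed statistic does, and takes the ``alpha_percentile`` of the
    resulting null r per voxel; adjusted_r = r_obs - that quantile, so
    adjusted_r > 0 only where the observed r exceeds its null quantile.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    tail = 1.0 - alpha_percentile / 100.0
    if n_perm * tail < 1:
        raise ValueError(
            f"n_perm={n_perm} too small to resolve the {alpha_percentile}th percentile"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    typicality = np.asarray(typicality, dtype=float).ravel()
    voxels = np.asarray(voxels, dtype=float)
    n = typicality.size
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    t_perm = typicality[perm_idx]  # (n_perm, n)
    t_perm_res = residualize(t_perm.T, covariate).T
    v_res = residualize(voxels, covariate)
    r_null = _corr_rows_with_matrix(t_perm_res, v_res)  # (n_perm, n_voxels)
    q = np.nanquantile(r_null, alpha_percentile / 100.0, axis=0)
    return np.asarray(r_obs, dtype=float) - q


@dataclass
class BrainMapResult:
    adjusted_r: np.ndarray  # subjects x voxels
    group_t: np.ndarray
    group_p: np.ndarray
    fwe_mask: np.ndarray
    excluded_voxels: np.ndarray
    n_perm: int
    alpha_percentile: float
    fwe_alpha: float
    fwe_method: str
    seed: int


def group_test(
    adjusted_r_by_subject: np.ndarray,
    fwe_alpha: float = 0.05,
    method: str = "bonferroni",
    n_perm: int = 2000,
    seed: int = 0,
    n_perm_null: int = 500,
    alpha_percentile: float = 95.0,
) -> BrainMapResult:
    """One-sample t of adjusted_r against 0 across subjects, per voxel,
    with family-wise error control over the tested voxel set.

    The test is one-sided for POSITIVE coupling: by construction the
    adjusted r of a null voxel sits below zero (its own null 95th
    percentile was subtracted), so only reliably positive means indicate
    coupling.  ``bonferroni`` thresholds the per-voxel one-sided p at
    ``fwe_alpha / n_voxels_tested``; ``maxstat`` compares each t against
    the permutation distribution of the maximum t under random sign flips
    of the subject maps.  Voxels with zero between-subject variance (or
    any NaN) are excluded and reported.
    """
    R = np.asarray(adjusted_r_by_subject, dtype=float)
    if R.ndim != 2 or R.shape[0] < 3:
        raise ValueError("need a subjects x voxels matrix with >= 3 subjects")
    n_subj, n_vox = R.shape
    sd = R.std(axis=0, ddof=1)
    excluded = np.flatnonzero(np.isnan(R).any(axis=0) | (sd == 0))
    if excluded.size:
        logger.info("excluding %d degenerate voxel(s) from the group test", excluded.size)
    valid = np.setdiff1d(np.arange(n_vox), excluded)
    t_map = np.full(n_vox, np.nan)
    p_map = np.full(n_vox, np.nan)
    mean = R[:, valid].mean(axis=0)
    se = sd[valid] / np.sqrt(n_subj)
    t_map[valid] = mean / se
    p_map[valid] = stats.t.sf(t_map[valid], n_subj - 1)
    fwe_mask = np.zeros(n_vox, dtype=bool)
    if method == "bonferroni":
        fwe_mask[valid] = p_map[valid] <= fwe_alpha / valid.size
    elif method == "maxstat":
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
        max_t = np.empty(n_perm)
        Rv = R[:, valid]
        for i in range(n_perm):
            flipped = signs[i][:, None] * Rv
            m = flipped.mean(axis=0)
            s = flipped.std(axis=0, ddof=1) / np.sqrt(n_subj)
            with np.errstate(divide="ignore", invalid="ignore"):
                max_t[i] = np.nanmax(m / s)
        thresh = np.quantile(max_t, 1.0 - fwe_alpha)
        fwe_mask[valid] = t_map[valid] > thresh
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    return BrainMapResult(
        adjusted_r=R,
        group_t=t_map,
        group_p=p_map,
        fwe_mask=fwe_mask,
        excluded_voxels=excluded,
        n_perm=n_perm if method == "maxstat" else 0,
        alpha_percentile=alpha_percentile,
        fwe_alpha=fwe_alpha,
        fwe_method=method,
        seed=seed,
    )
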