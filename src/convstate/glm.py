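"""Trial-level least-squares-all (LSA) GLM.

Every (trial, interval) event gets its own regressor: a boxcar convolved
with the canonical double-gamma HRF, sampled at the TR.  Ordinary least
squares per voxel yields one beta per trial and interval; betas are
converted to t-values (pooled residual variance per voxel) and then to
z-values via the inverse-normal transform of the two-sided Student-t
p-value, computed in log space so large |t| never overflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, special, stats

__all__ = [
    "canonical_hrf",
    "build_lsa_design",
    "fit_lsa",
    "t_to_z",
    "extract_roi",
    "LsaDesign",
    "TrialEstimates",
]

logger = logging.getLogger(__name__)

# canonical double-gamma parameters (response peak 6 s, undershoot peak
# 16 s, unit dispersions, undershoot ratio 1/6), kernel length 32 s
HRF_PARAMS = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_dispersion": 1.0,
    "undershoot_dispersion": 1.0,
    "undershoot_ratio": 1.0 / 6.0,
    "length_s": 32.0,
}


def canonical_hrf(dt: float, params: dict | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, peak-normalized."""
    p = dict(HRF_PARAMS)
    if params:
        p.update(params)
    t = np.arange(0.0, p["length_s"], dt)
    h = stats.gamma.pdf(t, p["peak_delay"] / p["peak_dispersion"], scale=p["peak_dispersion"]) - p[
        "undershoot_ratio"
    ] * stats.gamma.pdf(
        t, p["undershoot_delay"] / p["undershoot_dispersion"], scale=p["undershoot_dispersion"]
    )
    return h / h.max()


@dataclass
class LsaDesign:
    """LSA design matrix with one column per (trial, interval) event."""

    matrix: np.ndarray
    column_labels: list  # (trial_id, interval) tuples for task cols, str for others
    task_columns: np.ndarray  # integer indices of task columns
    hrf_params: dict
    dof: int
    tr_s: float

    @property
    def task_labels(self) -> list[tuple[str, str]]:
        return [self.column_labels[j] for j in self.task_columns]


_REQUIRED_EVENT_COLS = ("onset", "duration", "trial_id", "interval")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_EVENT_COLS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if (events["duration"] <= 0).any():
        bad = events.index[events["duration"] <= 0].tolist()
        raise ValueError(f"events with non-positive duration at rows {bad}")
    if (events["onset"] < 0).any():
        bad = events.index[events["onset"] < 0].tolist()
        raise ValueError(f"events with negative onset at rows {bad}")
    if not events["onset"].is_monotonic_increasing:
        events = events.sort_values("onset", kind="stable").reset_index(drop=True)
    return events


def build_lsa_design(
    events: pd.DataFrame,
    n_timepoints: int,
    tr_s: float,
    nuisance: np.ndarray | None = None,
    hrf_params: dict | None = None,
    oversample: int = 16,
    add_constant: bool = True,
    add_drift: bool = False,
) -> LsaDesign:
    """Build the least-squares-all design: one HRF-convolved boxcar per event.

    Boxcars are laid on a grid of ``tr_s / oversample`` seconds, convolved
    with the canonical HRF, then sampled at volume acquisition times
    ``t_i = i * tr_s``.  A constant column (and optionally a linear drift)
    is appended after any user-supplied nuisance columns.  Raises if the
    resulting matrix is rank deficient, naming the dependent columns.
    """
    events = validate_events(events)
    last_offset = float((events["onset"] + events["duration"]).max())
    if n_timepoints * tr_s < last_offset:
        raise ValueError(
            f"scan too short: {n_timepoints} volumes x {tr_s} s = "
            f"{n_timepoints * tr_s:.1f} s < last event offset {last_offset:.1f} s"
        )
    dt = tr_s / oversample
    n_hi = n_timepoints * oversample
    k = len(events)
    box = np.zeros((n_hi, k))
    onsets = events["onset"].to_numpy(float)
    durations = events["duration"].to_numpy(float)
    for j in range(k):
        i0 = int(round(onsets[j] / dt))
        i1 = max(i0 + 1, int(round((onsets[j] + durations[j]) / dt)))
        box[i0 : min(i1, n_hi), j] = 1.0
    kernel = canonical_hrf(dt, hrf_params)
    conv = signal.fftconvolve(box, kernel[:, None], axes=0)[:n_hi]
    task = conv[::oversample]

    labels: list = list(zip(events["trial_id"], events["interval"]))
    cols = [task]
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_timepoints:
            raise ValueError(
                f"nuisance has {nuisance.shape[0]} rows, expected {n_timepoints}"
            )
        cols.append(nuisance)
        labels += [f"nuisance_{i}" for i in range(nuisance.shape[1])]
    if add_drift:
        cols.append(np.linspace(-0.5, 0.5, n_timepoints)[:, None])
        labels.append("drift_linear")
    if add_constant:
        cols.append(np.ones((n_timepoints, 1)))
        labels.append("constant")
    X = np.hstack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the dependent ones
        from scipy.linalg import qr as scipy_qr

        _, _, piv = scipy_qr(X, mode="economic", pivoting=True)
        dependent = sorted(piv[rank:])
        names = [labels[j] for j in dependent]
        raise ValueError(
            f"design is rank deficient (rank {rank} of {X.shape[1]}); "
            f"collinear columns: {names}"
        )
    return LsaDesign(
        matrix=X,
        column_labels=labels,
        task_columns=np.arange(k),
        hrf_params=dict(HRF_PARAMS, **(hrf_params or {})),
        dof=n_timepoints - rank,
        tr_s=tr_s,
    )


@dataclass
class TrialEstimates:
    """Trial x voxel activation estimates for one interval (or all columns).

    ``beta``, ``t_value`` and ``z_value`` share the shape
    (n_task_columns x n_voxels); ``labels`` holds the (trial_id, interval)
    pair of each row.
    """

    beta: np.ndarray
    t_value: np.ndarray
    z_value: np.ndarray
    dof: int
    labels: list[tuple[str, str]]
    roi: str = "all"
    interval: str = "all"

    def select_interval(self, interval: str) -> "TrialEstimates":
        rows = [i for i, (_, iv) in enumerate(self.labels) if iv == interval]
        if not rows:
            raise ValueError(f"no rows with interval {interval!r}")
        return TrialEstimates(
            beta=self.beta[rows],
            t_value=self.t_value[rows],
            z_value=self.z_value[rows],
            dof=self.dof,
            labels=[self.labels[i] for i in rows],
            roi=self.roi,
            interval=interval,
        )


def fit_lsa(bold: np.ndarray, design: LsaDesign) -> TrialEstimates:
    """Ordinary least squares per voxel; t = beta / SE with pooled residual
    variance per voxel; z via :func:`t_to_z`.

    For a noiseless series that lies exactly in the column span, residuals
    are zero and the t/z values are reported as 0 with a log notice (the
    betas remain exact).
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 1:
        bold = bold[:, None]
    X = design.matrix
    if bold.shape[0] != X.shape[0]:
        raise ValueError(
            f"bold has {bold.shape[0]} timepoints but design has {X.shape[0]} rows"
        )
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rank checked earlier
        raise ValueError("singular normal equations") from exc
    beta_all = xtx_inv @ (X.T @ bold)
    resid = bold - X @ beta_all
    if design.dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("ij,ij->j", resid, resid) / design.dof
    se_all = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se_all > 0, beta_all / np.where(se_all > 0, se_all, 1.0), 0.0)
    if np.any(sigma2 == 0):
        logger.info(
            "%d voxel(s) with zero residual variance; t set to 0 there",
            int(np.sum(sigma2 == 0)),
        )
    task = design.task_columns
    beta = beta_all[task]
    t = t_all[task]
    z = t_to_z(t, design.dof)
    return TrialEstimates(
        beta=beta, t_value=t, z_value=z, dof=design.dof, labels=design.task_labels
    )


def t_to_z(t: np.ndarray | float, dof: int) -> np.ndarray | float:
    """Map Student-t values to standard-normal z preserving the two-sided p.

    z = sign(t) * Phi^-1(1 - p/2) with p the two-sided t tail probability;
    evaluated via log survival functions (scipy ``stats.t.logsf`` composed
    with ``special.ndtri_exp``) so that |t| up to several hundred maps to a
    finite z.
    """
    if dof < 1:
        raise ValueError(f"dof must be >= 1, got {dof}")
    t_arr = np.asarray(t, dtype=float)
    log_half_p = stats.t.logsf(np.abs(t_arr), dof)
    z = -special.ndtri_exp(log_half_p) * np.sign(t_arr)
    z = np.where(t_arr == 0, 0.0, z)
    return float(z) if np.isscalar(t) else z


def extract_roi(
    estimates: TrialEstimates, mask: np.ndarray, roi: str = "roi"
) -> TrialEstimates:
    """Restrict estimates to the voxel indices in ``mask`` (order preserved)."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = np.flatnonzero(mask)
    if mask.size == 0:
        raise ValueError("empty ROI mask")
    n_vox = estimates.beta.shape[1]
    if mask.min() < 0 or mask.max() >= n_vox:
        raise ValueError(
            f"mask indices out of range [0, {n_vox}): {mask.min()}..{mask.max()}"
        )
    return TrialEstimates(
        beta=estimates.beta[:, mask],
        t_value=estimates.t_value[:, mask],
        z_value=estimates.z_value[:, mask],
        dof=estimates.dof,
        labels=list(estimates.labels),
        roi=roi,
        interval=estimates.interval,
    )
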