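"""Trial-level univariate ROI summaries and the tidy modeling table.

Univariate and multivariate features are computed from the identical
z-valued pattern matrices — there is no separate univariate GLM — so the
two analyses always see the same data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import TRIAL_KEYS

__all__ = ["roi_mean", "build_univariate_table", "join_features"]


def roi_mean(estimates: np.ndarray) -> np.ndarray:
    """Arithmetic mean across voxels for each trial row."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.ndim != 2 or estimates.shape[1] < 1:
        raise ValueError("need a trials x voxels matrix with at least 1 voxel")
    return estimates.mean(axis=1)


def build_univariate_table(
    trials: pd.DataFrame, roi_matrices: dict[str, np.ndarray]
) -> pd.DataFrame:
    """One column of voxel-mean activation per ROI, keyed like the trial table."""
    out = trials[TRIAL_KEYS].copy()
    for roi, mat in roi_matrices.items():
        if len(mat) != len(trials):
            raise ValueError(
                f"ROI {roi!r} has {len(mat)} rows but the trial table has {len(trials)}"
            )
        out[f"uni_{roi}"] = roi_mean(mat)
    return out


def join_features(
    univariate: pd.DataFrame,
    typicality: pd.DataFrame,
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Merge trial table, univariate signals and typicality into one
    modeling table (one row per trial), validating key completeness.

    Raises with the orphan keys named if any table has rows the others
    lack; the joined row count always equals the trial-table row count.
    """
    for name, df in (("univariate", univariate), ("typicality", typicality)):
        missing = [k for k in TRIAL_KEYS if k not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing key columns {missing}")
    out = trials.copy()
    for name, df in (("univariate", univariate), ("typicality", typicality)):
        keys_left = set(map(tuple, out[TRIAL_KEYS].to_numpy()))
        keys_right = set(map(tuple, df[TRIAL_KEYS].to_numpy()))
        orphans = keys_left ^ keys_right
        if orphans:
            sample = sorted(orphans)[:10]
            raise ValueError(
                f"key mismatch joining {name}: {len(orphans)} orphan keys, e.g. {sample}"
            )
        out = out.merge(df, on=TRIAL_KEYS, how="inner", validate="one_to_one")
    if len(out) != len(trials):
        raise AssertionError("join changed the row count")  # pragma: no cover
    return out
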