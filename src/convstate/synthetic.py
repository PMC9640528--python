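"""Synthetic cohort generator.

Produces cohorts with the trial structure and statistical structure the
convergence analysis assumes: a trial table with hidden ground-truth
latents, multivoxel activation patterns whose correlation distance from a
prototypical state equals the planted eccentricity, binary recall outcomes
driven by those latents, and (optionally) BOLD time series so the
trial-level GLM stage can be exercised end to end.

Everything is a deterministic function of (spec, spec.seed): identical
specs yield bit-identical cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CohortSpec, child_rng

__all__ = [
    "SyntheticPatterns",
    "BoldRun",
    "generate_trial_table",
    "generate_memory_outcomes",
    "generate_patterns",
    "generate_grid",
    "generate_bold",
    "generate_cohort",
]

logger = logging.getLogger(__name__)

TRIAL_KEYS = ["subject_id", "run", "trial_in_run"]

# Latent eccentricity is mapped to a radial displacement so that the
# noise-free correlation distance from the prototype equals the latent
# exactly; values must stay below 1 for the mapping to be invertible.
_ECC_CAP = 0.95


@dataclass
class SyntheticPatterns:
    """Per-ROI trial patterns for one cohort.

    ``patterns[roi]`` is (n_trials_total x n_voxels) aligned row-for-row
    with the trial table; ``prototypes[roi]`` is (n_subjects x n_voxels).
    """

    patterns: dict[str, np.ndarray]
    prototypes: dict[str, np.ndarray]
    amplitude_by_trial: np.ndarray
    subjects: list[str] = field(default_factory=list)

    def subject_rows(self, table: pd.DataFrame, subject_id: str) -> np.ndarray:
        rows = np.flatnonzero(table["subject_id"].to_numpy() == subject_id)
        if rows.size == 0:
            raise KeyError(f"unknown subject {subject_id!r}")
        return rows


@dataclass
class BoldRun:
    """One run's simulated BOLD: (timepoints x voxels) plus its events."""

    data: np.ndarray
    events: pd.DataFrame
    tr_s: float
    roi_slices: dict[str, slice]
    subject_id: str
    run: int


def _subject_ids(spec: CohortSpec) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(spec.n_subjects)]


def generate_trial_table(spec: CohortSpec) -> pd.DataFrame:
    """Generate the cohort trial table with timing and hidden latents.

    Each subject completes ``spec.n_runs`` runs of
    ``spec.trials_per_condition_per_run`` trials per condition in a
    randomized order.  The anticipation delay of each trial is drawn from
    ``spec.anticipation_delays_s``; inter-trial intervals are uniform over
    ``spec.iti_range_s``.  Hidden columns ``latent_modulator`` (VTA-like
    scalar: subject mean + unit trial noise) and ``latent_eccentricity``
    (ground-truth distance from the prototypical state) drive the pattern
    and memory generators.
    """
    rng = child_rng(spec.seed, "trial_table")
    lo_iti, hi_iti = spec.iti_range_s
    delays = np.asarray(spec.anticipation_delays_s, dtype=float)
    rows = []
    for subj in _subject_ids(spec):
        subj_mod = spec.subject_modulator_sd * rng.standard_normal()
        subj_ecc = spec.subject_eccentricity_sd * rng.standard_normal()
        for run in range(1, spec.n_runs + 1):
            conds = np.repeat(spec.conditions, spec.trials_per_condition_per_run)
            rng.shuffle(conds)
            t = float(rng.uniform(lo_iti, hi_iti))
            for idx, cond in enumerate(conds, start=1):
                delay = float(rng.choice(delays))
                modulator = subj_mod + rng.standard_normal()
                ecc = (
                    spec.eccentricity_base
                    + subj_ecc
                    + spec.eccentricity_condition_shift * (cond == spec.conditions[0])
                    + spec.modulator_typicality_slope * modulator
                    + spec.eccentricity_noise_sd * rng.standard_normal()
                )
                # high/low indicator: conditions[0] is the high-curiosity label
                rating_lo, rating_hi = (66.0, 100.0) if cond == "high" else (0.0, 33.0)
                rows.append(
                    {
                        "subject_id": subj,
                        "run": run,
                        "trial_in_run": idx,
                        "condition": str(cond),
                        "curiosity_rating": float(rng.uniform(rating_lo, rating_hi)),
                        "onset_question_s": t,
                        "delay_s": delay,
                        "onset_answer_s": t + delay,
                        "latent_modulator": modulator,
                        "latent_eccentricity": max(0.0, ecc),
                    }
                )
                t = t + delay + spec.answer_duration_s + float(rng.uniform(lo_iti, hi_iti))
    table = pd.DataFrame(rows)
    table["recalled"] = np.nan
    return table


def generate_memory_outcomes(table: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Draw binary recall outcomes from the planted logistic memory model.

    log-odds = condition intercept + subject intercept
               + (memory_typicality_slope + subject slope) * eccentricity
               + memory_modulator_slope * modulator
    """
    if table["latent_eccentricity"].isna().any():
        raise ValueError("latent columns must be populated before memory generation")
    rng = child_rng(spec.seed, "memory")
    out = table.copy()
    intercept = out["condition"].map(spec.memory_intercept_by_condition).to_numpy(float)
    subjects = out["subject_id"].to_numpy()
    uniq = pd.unique(subjects)
    subj_int = {
        s: spec.memory_subject_sd * rng.standard_normal() for s in uniq
    }
    subj_slope = {
        s: spec.memory_typicality_slope_subject_sd * rng.standard_normal() for s in uniq
    }
    eta = (
        intercept
        + np.array([subj_int[s] for s in subjects])
        + (
            spec.memory_typicality_slope
            + np.array([subj_slope[s] for s in subjects])
        )
        * out["latent_eccentricity"].to_numpy()
        + spec.memory_modulator_slope * out["latent_modulator"].to_numpy()
    )
    out["recall_probability"] = expit(eta)
    out["recalled"] = (rng.uniform(size=len(out)) < out["recall_probability"]).astype(int)
    return out


def _orthogonal_unit_directions(
    rng: np.random.Generator, n: int, prototype_centered: np.ndarray
) -> np.ndarray:
    """n random zero-mean unit directions orthogonal to the centered prototype."""
    v = prototype_centered
    nv2 = float(v @ v)
    u = rng.standard_normal((n, v.size))
    u -= u.mean(axis=1, keepdims=True)
    u -= np.outer(u @ v / nv2, v)
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    if np.any(norms == 0):  # pragma: no cover - probability zero
        raise RuntimeError("degenerate random direction")
    return u / norms


def _displacement_for_distance(e: np.ndarray, proto_norm: float) -> np.ndarray:
    """Radial displacement giving noise-free correlation distance ``e``.

    For a pattern p + c*u with u a zero-mean unit vector orthogonal to the
    centered prototype p~, the Pearson r with the prototype is
    ||p~|| / sqrt(||p~||^2 + c^2); solving 1 - r = e gives
    c = ||p~|| * sqrt((1-e)^-2 - 1).
    """
    e = np.clip(e, 0.0, _ECC_CAP)
    return proto_norm * np.sqrt((1.0 - e) ** -2 - 1.0)


def generate_patterns(
    table: pd.DataFrame,
    spec: CohortSpec,
    rois: list[str] | None = None,
) -> SyntheticPatterns:
    """Generate per-ROI multivoxel patterns realizing the planted geometry.

    For each subject and ROI a fixed random prototype vector is drawn.  The
    ROI named ``spec.eccentricity_roi`` displaces each trial's pattern away
    from the prototype along a trial-unique orthogonal direction by exactly
    the trial's latent eccentricity (in correlation-distance units, before
    voxel noise); other pattern ROIs receive independent null eccentricity
    draws with the same base and noise but no condition or modulator
    dependence.  The ROI named ``spec.modulator_roi`` instead encodes the
    latent modulator as a uniform activation offset, so its voxel mean
    recovers the modulator up to noise of sd pattern_noise_sd/sqrt(V).
    """
    rois = list(spec.n_voxels_by_roi) if rois is None else list(rois)
    unknown = [r for r in rois if r not in spec.n_voxels_by_roi]
    if unknown:
        raise ValueError(f"unknown ROI(s) {unknown}; spec defines {list(spec.n_voxels_by_roi)}")
    for roi in rois:
        if roi != spec.modulator_roi and spec.n_voxels_by_roi[roi] < 3:
            raise ValueError(
                f"ROI {roi!r} has {spec.n_voxels_by_roi[roi]} voxels; "
                "correlation distance needs at least 3"
            )
    rng = child_rng(spec.seed, "patterns")
    subjects = _subject_ids(spec)
    n_total = len(table)
    patterns = {roi: np.empty((n_total, spec.n_voxels_by_roi[roi])) for roi in rois}
    prototypes = {
        roi: np.empty((spec.n_subjects, spec.n_voxels_by_roi[roi])) for roi in rois
    }
    subj_col = table["subject_id"].to_numpy()
    ecc_all = table["latent_eccentricity"].to_numpy()
    mod_all = table["latent_modulator"].to_numpy()
    for si, subj in enumerate(subjects):
        rows = np.flatnonzero(subj_col == subj)
        n = rows.size
        for roi in rois:
            nv = spec.n_voxels_by_roi[roi]
            proto = spec.prototype_scale * rng.standard_normal(nv)
            prototypes[roi][si] = proto
            noise = spec.pattern_noise_sd * rng.standard_normal((n, nv))
            if roi == spec.modulator_roi:
                pat = proto[None, :] + mod_all[rows, None] + noise
            else:
                if roi == spec.eccentricity_roi:
                    ecc = ecc_all[rows]
                else:
                    ecc = np.maximum(
                        0.0,
                        spec.eccentricity_base
                        + spec.eccentricity_noise_sd * rng.standard_normal(n),
                    )
                centered = proto - proto.mean()
                c = _displacement_for_distance(ecc, float(np.linalg.norm(centered)))
                u = _orthogonal_unit_directions(rng, n, centered)
                pat = proto[None, :] + c[:, None] * u + noise
            patterns[roi][rows] = pat
    return SyntheticPatterns(
        patterns=patterns,
        prototypes=prototypes,
        amplitude_by_trial=np.ones(n_total),
        subjects=subjects,
    )


def generate_grid(
    table: pd.DataFrame, spec: CohortSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Trialwise univariate activation over a flat synthetic voxel grid.

    Returns ``(grid, coupled_idx)`` where ``grid`` is
    (n_trials_total x n_grid_voxels) of iid noise, and the voxels in
    ``coupled_idx`` (the first ``n_coupled_voxels``) additionally carry
    ``grid_coupling`` times the within-subject standardized latent
    eccentricity.  With ``grid_coupling = 0`` the grid is globally null.
    """
    if spec.n_grid_voxels == 0:
        raise ValueError("spec.n_grid_voxels is 0; no grid to generate")
    rng = child_rng(spec.seed, "grid")
    n = len(table)
    grid = spec.grid_noise_sd * rng.standard_normal((n, spec.n_grid_voxels))
    coupled = np.arange(spec.n_coupled_voxels)
    if spec.grid_coupling != 0.0 and spec.n_coupled_voxels > 0:
        ecc = table["latent_eccentricity"].to_numpy()
        z = np.empty_like(ecc)
        for subj, idx in table.groupby("subject_id", sort=False).indices.items():
            e = ecc[idx]
            sd = e.std()
            z[idx] = (e - e.mean()) / sd if sd > 0 else 0.0
        grid[:, coupled] += spec.grid_coupling * z[:, None]
    return grid, coupled


def make_run_events(
    table: pd.DataFrame, spec: CohortSpec, subject_id: str, run: int,
    question_epoch: str = "anticipation",
) -> pd.DataFrame:
    """BIDS-style event table (onset, duration, trial_id, interval) for one run.

    The question regressor spans the anticipation epoch (question onset to
    answer onset) by default; ``"stim"`` restricts it to the question
    presentation, ``"impulse"`` to a brief 0.1 s event.
    """
    sel = table[(table["subject_id"] == subject_id) & (table["run"] == run)]
    if sel.empty:
        raise KeyError(f"no trials for subject {subject_id!r} run {run}")
    events = []
    for _, tr in sel.iterrows():
        if question_epoch == "anticipation":
            qdur = tr["delay_s"]
        elif question_epoch == "stim":
            qdur = spec.question_duration_s
        elif question_epoch == "impulse":
            qdur = 0.1
        else:
            raise ValueError(f"unknown question_epoch {question_epoch!r}")
        trial_id = f"{subject_id}_r{run:02d}_t{int(tr['trial_in_run']):03d}"
        events.append(
            {
                "onset": tr["onset_question_s"],
                "duration": qdur,
                "trial_id": trial_id,
                "interval": "question",
                "run": run,
            }
        )
        events.append(
            {
                "onset": tr["onset_answer_s"],
                "duration": spec.answer_duration_s,
                "trial_id": trial_id,
                "interval": "answer",
                "run": run,
            }
        )
    ev = pd.DataFrame(events).sort_values("onset", kind="stable").reset_index(drop=True)
    # boxcars of the same interval type overlapping in time signals a
    # mis-specified design; tolerated with a warning, never an error
    for iv, g in ev.groupby("interval"):
        ons = g["onset"].to_numpy()
        offs = ons + g["duration"].to_numpy()
        if np.any(ons[1:] < offs[:-1] - 1e-9):
            warnings.warn(
                f"overlapping {iv} events in {subject_id} run {run}; "
                "design may be poorly conditioned"
            )
    return ev


def generate_bold(
    table: pd.DataFrame,
    patterns: SyntheticPatterns,
    spec: CohortSpec,
    subjects: list[str] | None = None,
    question_epoch: str = "anticipation",
) -> dict[tuple[str, int], BoldRun]:
    """Simulate per-run BOLD series from trial amplitudes and patterns.

    Each (trial, interval) boxcar is convolved with the canonical
    double-gamma HRF and scaled, voxel by voxel, by that trial's pattern
    value (question interval) or the subject prototype (answer interval),
    multiplied by the trial amplitude; Gaussian noise of sd
    ``spec.bold_noise_sd`` is added.  Run length covers the last event
    plus 20 s.
    """
    from .glm import build_lsa_design  # deferred: avoids import cycle

    rng = child_rng(spec.seed, "bold")
    rois = list(patterns.patterns)
    roi_slices: dict[str, slice] = {}
    off = 0
    for roi in rois:
        nv = spec.n_voxels_by_roi[roi]
        roi_slices[roi] = slice(off, off + nv)
        off += nv
    n_vox = off
    out: dict[tuple[str, int], BoldRun] = {}
    subjects = patterns.subjects if subjects is None else subjects
    subj_col = table["subject_id"].to_numpy()
    run_col = table["run"].to_numpy()
    for si, subj in enumerate(subjects):
        for run in range(1, spec.n_runs + 1):
            rows = np.flatnonzero((subj_col == subj) & (run_col == run))
            events = make_run_events(table, spec, subj, run, question_epoch)
            t_end = float((events["onset"] + events["duration"]).max()) + 20.0
            n_tp = int(np.ceil(t_end / spec.tr_seconds))
            design = build_lsa_design(events, n_tp, spec.tr_seconds)
            # amplitude matrix: one row per task column, one col per voxel
            amp = np.zeros((len(design.task_labels), n_vox))
            trial_ids = [
                f"{subj}_r{run:02d}_t{int(t):03d}"
                for t in table["trial_in_run"].to_numpy()[rows]
            ]
            row_of_trial = dict(zip(trial_ids, rows))
            for k, (tid, interval) in enumerate(design.task_labels):
                trow = row_of_trial[tid]
                a = patterns.amplitude_by_trial[trow]
                for roi in rois:
                    if interval == "question":
                        vals = patterns.patterns[roi][trow]
                    else:
                        vals = patterns.prototypes[roi][si]
                    amp[k, roi_slices[roi]] = a * vals
            X = design.matrix[:, design.task_columns]
            data = X @ amp
            if spec.bold_noise_sd > 0:
                data = data + spec.bold_noise_sd * rng.standard_normal(data.shape)
            out[(subj, run)] = BoldRun(
                data=data,
                events=events,
                tr_s=spec.tr_seconds,
                roi_slices=roi_slices,
                subject_id=subj,
                run=run,
            )
    return out


def generate_cohort(
    spec: CohortSpec, rois: list[str] | None = None
) -> tuple[pd.DataFrame, SyntheticPatterns]:
    """Trial table with outcomes plus patterns, in one call."""
    table = generate_memory_outcomes(generate_trial_table(spec), spec)
    return table, generate_patterns(table, spec, rois=rois)
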