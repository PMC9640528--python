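"""Configuration objects for the synthetic cohort and the analysis pipeline.

The central object is :class:`CohortSpec`, whose defaults encode the study
design this package emulates: 23 participants, 6 scanner runs, 12 high- and
12 low-curiosity trivia trials per run, a 4 s question followed by a 9 s or
13 s anticipation period and a 1 s answer, TR = 2 s.  All planted effect
sizes (condition shift on pattern eccentricity, modulator->eccentricity
slope, eccentricity->memory and modulator->memory log-odds) live here so a
single spec + seed fully determines a cohort.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "CohortSpec",
    "PipelineConfig",
    "child_rng",
    "child_seed",
    "marginal_recall_probability",
    "calibrate_memory_intercept",
]

# target marginal recall rates the default intercepts are calibrated to
_TARGET_RECALL = {"high": 0.63, "low": 0.40}
_DEFAULT_MEMORY_SUBJECT_SD = 0.7

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(40)


def marginal_recall_probability(intercept: float, subject_sd: float) -> float:
    """Expected recall rate E_z[expit(intercept + subject_sd * z)], z ~ N(0,1).

    Evaluated with 40-node Gauss-Hermite quadrature; exact enough for
    calibration purposes (absolute error < 1e-10).
    """
    z = np.sqrt(2.0) * _GH_NODES
    vals = expit(intercept + subject_sd * z)
    return float(np.sum(_GH_WEIGHTS * vals) / np.sqrt(np.pi))


def calibrate_memory_intercept(p: float, subject_sd: float) -> float:
    """Log-odds intercept whose marginal recall rate equals ``p``.

    Inverts :func:`marginal_recall_probability` over the subject
    random-intercept distribution, so that a cohort with zero slopes
    realizes recall rate ``p`` in each condition on average.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"recall probability must be in (0,1), got {p}")
    return float(
        brentq(lambda mu: marginal_recall_probability(mu, subject_sd) - p, -15.0, 15.0)
    )


def _default_memory_intercepts() -> dict[str, float]:
    return {
        cond: calibrate_memory_intercept(p, _DEFAULT_MEMORY_SUBJECT_SD)
        for cond, p in _TARGET_RECALL.items()
    }


def child_seed(top_seed: int, stage: str) -> np.random.SeedSequence:
    """Stage-specific seed derived from the top-level seed.

    Uses a stable hash of the stage name so that adding or reordering
    stages never perturbs the random streams of the others.
    """
    return np.random.SeedSequence([int(top_seed), zlib.crc32(stage.encode("utf-8"))])


def child_rng(top_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(top_seed, stage))


@dataclass
class CohortSpec:
    """Design constants and planted effect sizes for one synthetic cohort.

    Trial structure
    ---------------
    ``n_subjects`` participants each complete ``n_runs`` runs containing
    ``trials_per_condition_per_run`` trials of each curiosity condition in
    randomized order.  Each trial shows a question for
    ``question_duration_s`` seconds, the answer appears after a delay drawn
    from ``anticipation_delays_s``, stays for ``answer_duration_s`` seconds,
    and is followed by an inter-trial interval drawn uniformly from
    ``iti_range_s`` (the active-baseline counting period).

    Planted structure
    -----------------
    Each trial carries a latent modulator (a VTA-like scalar,
    subject mean sd ``subject_modulator_sd`` plus unit trial noise) and a
    latent eccentricity (the ground-truth distance of that trial's pattern
    from the prototypical state)::

        ecc = max(0, eccentricity_base + subject_offset
                     + eccentricity_condition_shift * [condition == high]
                     + modulator_typicality_slope * modulator
                     + eccentricity_noise_sd * N(0,1))

    Recall is Bernoulli with log-odds::

        memory_intercept_by_condition[cond] + subject_intercept
            + memory_typicality_slope * ecc
            + memory_modulator_slope * modulator

    ``eccentricity_roi`` is the ROI whose patterns realize the trial latent
    (hippocampus by default); other pattern ROIs receive independent null
    eccentricity draws; ``modulator_roi`` realizes the modulator as a
    uniform activation offset so its ROI mean recovers the latent scalar.

    The grid fields describe a flat voxel "volume" with a small region whose
    univariate activation is coupled to the trial eccentricity, exercising
    the permutation-null correlation map.
    """

    n_subjects: int = 23
    n_runs: int = 6
    trials_per_condition_per_run: int = 12
    conditions: tuple[str, ...] = ("high", "low")
    n_voxels_by_roi: dict[str, int] = field(
        default_factory=lambda: {"VTA": 100, "HPC": 300, "PHC": 150, "PRC": 150}
    )

    tr_seconds: float = 2.0
    question_duration_s: float = 4.0
    anticipation_delays_s: tuple[float, ...] = (9.0, 13.0)
    answer_duration_s: float = 1.0
    iti_range_s: tuple[float, float] = (1.0, 20.0)

    prototype_scale: float = 1.0
    eccentricity_base: float = 0.5
    eccentricity_condition_shift: float = -0.02
    eccentricity_noise_sd: float = 0.15
    subject_eccentricity_sd: float = 0.02
    modulator_typicality_slope: float = -0.06
    subject_modulator_sd: float = 0.3

    memory_intercept_by_condition: dict[str, float] = field(
        default_factory=_default_memory_intercepts
    )
    memory_typicality_slope: float = -0.6
    memory_modulator_slope: float = 0.15
    memory_subject_sd: float = _DEFAULT_MEMORY_SUBJECT_SD
    memory_typicality_slope_subject_sd: float = 0.0

    pattern_noise_sd: float = 0.5
    bold_noise_sd: float = 1.0

    eccentricity_roi: str = "HPC"
    modulator_roi: str = "VTA"

    n_grid_voxels: int = 2000
    n_coupled_voxels: int = 50
    grid_coupling: float = 0.5
    grid_noise_sd: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_runs", "trials_per_condition_per_run"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")
        for roi, v in self.n_voxels_by_roi.items():
            if v < 1:
                raise ValueError(f"n_voxels_by_roi[{roi!r}] must be >= 1, got {v}")
        for name in (
            "tr_seconds",
            "question_duration_s",
            "answer_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.anticipation_delays_s:
            raise ValueError("anticipation_delays_s must be non-empty")
        if min(self.anticipation_delays_s) <= self.question_duration_s:
            raise ValueError(
                "anticipation delay must exceed the question duration "
                "(the answer onset follows the question onset by the delay)"
            )
        lo, hi = self.iti_range_s
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid iti_range_s {self.iti_range_s}")
        for name in (
            "eccentricity_base",
            "eccentricity_noise_sd",
            "subject_eccentricity_sd",
            "subject_modulator_sd",
            "memory_subject_sd",
            "memory_typicality_slope_subject_sd",
            "pattern_noise_sd",
            "bold_noise_sd",
            "grid_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        missing = [c for c in self.conditions if c not in self.memory_intercept_by_condition]
        if missing:
            raise ValueError(f"memory_intercept_by_condition missing {missing}")
        if self.n_grid_voxels < 0 or self.n_coupled_voxels < 0:
            raise ValueError("grid voxel counts must be non-negative")
        if self.n_coupled_voxels > self.n_grid_voxels:
            raise ValueError("n_coupled_voxels cannot exceed n_grid_voxels")

    # ----- convenience -------------------------------------------------

    @property
    def trials_per_run(self) -> int:
        return self.trials_per_condition_per_run * len(self.conditions)

    @property
    def n_trials_total(self) -> int:
        return self.n_subjects * self.n_runs * self.trials_per_run

    def pattern_rois(self) -> list[str]:
        return list(self.n_voxels_by_roi)

    def replace(self, **kwargs: Any) -> "CohortSpec":
        d = self.to_dict()
        d.update(kwargs)
        return CohortSpec.from_dict(d)

    # ----- (de)serialization -------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        for key in ("conditions", "anticipation_delays_s", "iti_range_s"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortSpec":
        d = dict(d)
        for key in ("conditions", "anticipation_delays_s", "iti_range_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(text))


def null_cohort_spec(seed: int = 0, **overrides: Any) -> CohortSpec:
    """A cohort spec with every planted effect zeroed (global null).

    Subject-level nuisance heterogeneity (random intercepts, subject
    modulator means) is retained: those are properties of the data the
    models must absorb, not effects under test.
    """
    base = CohortSpec(
        eccentricity_condition_shift=0.0,
        modulator_typicality_slope=0.0,
        memory_typicality_slope=0.0,
        memory_modulator_slope=0.0,
        grid_coupling=0.0,
        seed=seed,
    )
    return base.replace(**overrides) if overrides else base


@dataclass
class PipelineConfig:
    """Full configuration of the simulate -> glm -> converge -> model ->
    permmap pipeline.  Serializes losslessly to/from YAML; every stochastic
    stage derives its seed from ``seed`` and its stage name."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    mode: str = "pattern"  # {"pattern", "bold"}
    # GLM options
    question_epoch: str = "anticipation"  # {"anticipation", "stim", "impulse"}
    glm_statistic: str = "z"  # {"z", "beta"}
    add_drift: bool = False
    # convergence options
    centroid_method: str = "kmeans_mean"  # {"kmeans_mean", "medoid"}
    outlier_threshold_sd: float = 3.0
    interval: str = "question"  # {"question", "answer"}
    # inference options
    n_boot_mediation: int = 1000
    random_slopes: str = "auto"  # {"auto", "never", "always"}
    # permutation-map options
    n_perm: int = 500
    alpha_percentile: float = 95.0
    fwe_alpha: float = 0.05
    fwe_method: str = "bonferroni"  # {"bonferroni", "maxstat"}
    run_permmap: bool = True
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("pattern", "bold"):
            raise ValueError(f"mode must be 'pattern' or 'bold', got {self.mode!r}")
        if self.question_epoch not in ("anticipation", "stim", "impulse"):
            raise ValueError(f"unknown question_epoch {self.question_epoch!r}")
        if self.glm_statistic not in ("z", "beta"):
            raise ValueError(f"glm_statistic must be 'z' or 'beta'")
        if self.centroid_method not in ("kmeans_mean", "medoid"):
            raise ValueError(f"unknown centroid_method {self.centroid_method!r}")
        if self.interval not in ("question", "answer"):
            raise ValueError(f"interval must be 'question' or 'answer'")
        if self.n_boot_mediation < 1:
            raise ValueError("n_boot_mediation must be >= 1")
        if self.random_slopes not in ("auto", "never", "always"):
            raise ValueError(f"unknown random_slopes policy {self.random_slopes!r}")
        if not 0.0 < self.alpha_percentile < 100.0:
            raise ValueError("alpha_percentile must be in (0, 100)")
        if self.fwe_method not in ("bonferroni", "maxstat"):
            raise ValueError(f"unknown fwe_method {self.fwe_method!r}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortSpec.from_dict(d["cohort"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))
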