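"""End-to-end orchestration: simulate -> (glm) -> converge -> univariate ->
model -> permmap -> report.

Every stage derives its random stream from the top-level seed and its
stage name, writes its outputs under the run directory, and the final
manifest records a checksum for each file, so two runs with the same
config are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import convergence, features, glm, inference, io, permmap, synthetic
from .config import CohortSpec, PipelineConfig, child_seed

__all__ = ["run_pipeline", "PipelineResult", "analyze_patterns", "measure_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    outdir: Path
    trial_table: pd.DataFrame
    modeling_table: pd.DataFrame
    results: dict
    files: list[Path] = field(default_factory=list)


def _setup_logging(outdir: Path, level: str) -> None:
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO))
    root = logging.getLogger("convstate")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    if not any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", "").startswith(str(outdir))
        for h in root.handlers
    ):
        fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)


def _glm_patterns(
    table: pd.DataFrame,
    patterns: synthetic.SyntheticPatterns,
    spec: CohortSpec,
    config: PipelineConfig,
) -> dict[str, np.ndarray]:
    """BOLD mode: simulate runs, fit the LSA GLM, return trials x voxels
    statistic matrices per ROI aligned with the trial table."""
    bold = synthetic.generate_bold(
        table, patterns, spec, question_epoch=config.question_epoch
    )
    rois = list(patterns.patterns)
    out = {
        roi: np.full((len(table), spec.n_voxels_by_roi[roi]), np.nan) for roi in rois
    }
    row_of = {
        f"{s}_r{r:02d}_t{t:03d}": i
        for i, (s, r, t) in enumerate(
            zip(table["subject_id"], table["run"], table["trial_in_run"])
        )
    }
    for (subj, run), br in bold.items():
        design = glm.build_lsa_design(
            br.events,
            br.data.shape[0],
            br.tr_s,
            add_drift=config.add_drift,
        )
        est = glm.fit_lsa(br.data, design)
        stat = est.z_value if config.glm_statistic == "z" else est.beta
        interval = config.interval
        for k, (tid, iv) in enumerate(est.labels):
            if iv != interval:
                continue
            row = row_of[tid]
            for roi in rois:
                out[roi][row] = stat[k, br.roi_slices[roi]]
    for roi in rois:
        if np.isnan(out[roi]).any():
            raise RuntimeError(f"GLM stage left unfilled trials for ROI {roi}")
    return out


def analyze_patterns(
    table: pd.DataFrame,
    roi_matrices: dict[str, np.ndarray],
    spec: CohortSpec,
    centroid_method: str = "kmeans_mean",
    outlier_threshold_sd: float = 3.0,
) -> pd.DataFrame:
    """Convergence + univariate stages on trial-aligned ROI matrices.

    Computes leave-one-run-out typicality per subject for every pattern
    ROI (the modulator ROI contributes a univariate mean only), z-scores
    within subject, flags outliers on the eccentricity ROI, and joins
    everything into the tidy modeling table (one row per trial).
    """
    typ_rois = [r for r in roi_matrices if r != spec.modulator_roi]
    typ = table[synthetic.TRIAL_KEYS].copy()
    subj_col = table["subject_id"].to_numpy()
    runs = table["run"].to_numpy()
    for roi in typ_rois:
        dist = np.full(len(table), np.nan)
        for subj in pd.unique(subj_col):
            rows = np.flatnonzero(subj_col == subj)
            tt, _ = convergence.loro_typicality(
                roi_matrices[roi][rows], runs[rows], method=centroid_method
            )
            dist[rows] = tt["distance"].to_numpy()
        typ[f"dist_{roi}"] = dist
        typ = convergence.zscore_within_subject(
            typ, value_col=f"dist_{roi}", out_col=f"zdist_{roi}"
        )
    focal = f"zdist_{spec.eccentricity_roi}"
    if focal in typ.columns:
        typ = convergence.flag_outliers(typ, outlier_threshold_sd, z_col=focal)
    uni = features.build_univariate_table(table, roi_matrices)
    return features.join_features(uni, typ, table)


def _model_stage(
    modeling: pd.DataFrame, spec: CohortSpec, config: PipelineConfig
) -> dict:
    """Fit the standard model set on the modeling table."""
    ecc_roi = spec.eccentricity_roi
    mod_roi = spec.modulator_roi
    typ_rois = [
        r for r in spec.pattern_rois() if r != mod_roi and f"dist_{r}" in modeling.columns
    ]
    results: dict = {}

    results["recall_contrast"] = vars(inference.recall_contrast(modeling))

    results["condition_effects"] = {}
    for roi in typ_rois:
        eff = inference.fit_condition_effect(
            modeling, f"dist_{roi}", random_slopes=config.random_slopes
        )
        results["condition_effects"][roi] = vars(eff)
    results["condition_effects_univariate"] = {}
    for roi in spec.pattern_rois():
        col = f"uni_{roi}"
        if col in modeling.columns:
            eff = inference.fit_condition_effect(
                modeling, col, random_slopes=config.random_slopes
            )
            results["condition_effects_univariate"][roi] = vars(eff)

    uni_mod = f"uni_{mod_roi}"
    if uni_mod in modeling.columns:
        eff = inference.fit_continuous_effect(
            modeling,
            f"dist_{ecc_roi}",
            uni_mod,
            random_slopes=config.random_slopes,
            term_name=f"{uni_mod}->dist_{ecc_roi}",
        )
        results["modulator_typicality"] = vars(eff)

    mem_predictors = [f"dist_{r}" for r in typ_rois]
    if uni_mod in modeling.columns:
        mem_predictors.append(uni_mod)
    effects, full = inference.fit_memory_model(modeling, mem_predictors)
    results["memory_model"] = {e.term: vars(e) for e in effects}

    # robustness recipe: curiosity condition as covariate
    cov = modeling.assign(cond_high=(modeling["condition"] == "high").astype(float))
    effects_cov, _ = inference.fit_memory_model(cov, mem_predictors + ["cond_high"])
    results["memory_model_condition_covaried"] = {e.term: vars(e) for e in effects_cov}

    if uni_mod in modeling.columns:
        # does HPC typicality add to VTA activation, and vice versa?
        _, m_vta = inference.fit_memory_model(modeling, [uni_mod])
        _, m_typ = inference.fit_memory_model(modeling, [f"dist_{ecc_roi}"])
        _, m_both = inference.fit_memory_model(modeling, [uni_mod, f"dist_{ecc_roi}"])
        results["lrt_typicality_over_modulator"] = vars(
            inference.lrt_select(m_vta, m_both, labels=("modulator_only", "both"))
        )
        results["lrt_modulator_over_typicality"] = vars(
            inference.lrt_select(m_typ, m_both, labels=("typicality_only", "both"))
        )
        med = inference.mediate(
            modeling,
            treatment=uni_mod,
            mediator=f"dist_{ecc_roi}",
            n_boot=config.n_boot_mediation,
            seed=int(child_seed(config.seed, "mediation").generate_state(1)[0] % (2**31)),
        )
        results["mediation"] = vars(med)

        per_subj = modeling.groupby("subject_id", sort=True).agg(
            vta=(uni_mod, "mean"), dist=(f"dist_{ecc_roi}", "mean")
        )
        results["subject_correlation"] = vars(
            inference.subject_correlation(per_subj["vta"], per_subj["dist"])
        )
    _ = full
    return results


def _permmap_stage(
    table: pd.DataFrame, modeling: pd.DataFrame, spec: CohortSpec, config: PipelineConfig
) -> tuple[dict, np.ndarray, permmap.BrainMapResult]:
    grid, coupled = synthetic.generate_grid(table, spec)
    ecc_col = f"dist_{spec.eccentricity_roi}"
    cov_col = f"uni_{spec.modulator_roi}"
    subj_col = modeling["subject_id"].to_numpy()
    subjects = pd.unique(subj_col)
    seed0 = int(child_seed(config.seed, "permmap").generate_state(1)[0] % (2**31))
    adj = np.empty((len(subjects), grid.shape[1]))
    for si, subj in enumerate(subjects):
        rows = np.flatnonzero(subj_col == subj)
        typ = modeling[ecc_col].to_numpy()[rows]
        cov = modeling[cov_col].to_numpy()[rows] if cov_col in modeling.columns else None
        V = grid[rows]
        r_obs = permmap.voxelwise_r(typ, V, cov)
        adj[si] = permmap.null_adjust(
            r_obs,
            typ,
            V,
            cov,
            n_perm=config.n_perm,
            alpha_percentile=config.alpha_percentile,
            seed=np.random.default_rng(seed0 + si),
        )
    bm = permmap.group_test(
        adj, fwe_alpha=config.fwe_alpha, method=config.fwe_method, seed=seed0
    )
    n_surv = int(bm.fwe_mask.sum())
    summary = {
        "n_voxels": int(grid.shape[1]),
        "n_coupled_planted": int(coupled.size),
        "positive_fraction_mean": float(np.mean(adj > 0)),
        "n_fwe_voxels": n_surv,
        "n_fwe_in_planted": int(bm.fwe_mask[coupled].sum()) if coupled.size else 0,
    }
    return summary, coupled, bm


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute the configured stages in dependency order.

    Writes trial_table.csv, typicality/modeling tables, results.json, a
    per-voxel permutation-map table (when enabled), and a manifest with
    content checksums.  Reruns with identical config and seed produce
    byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    spec = config.cohort.replace(seed=config.seed)
    files: list[Path] = []

    logger.info("stage simulate: %d subjects x %d runs", spec.n_subjects, spec.n_runs)
    table, patterns = synthetic.generate_cohort(spec)
    files.append(io.write_trial_table(table, outdir / "trial_table.csv"))

    if config.mode == "bold":
        logger.info("stage glm: least-squares-all fit per run")
        events_dir = outdir / "events"
        events_dir.mkdir(exist_ok=True)
        for subj in patterns.subjects:
            for run in range(1, spec.n_runs + 1):
                ev = synthetic.make_run_events(
                    table, spec, subj, run, config.question_epoch
                )
                files.append(
                    io.write_events_tsv(ev, events_dir / f"{subj}_run-{run:02d}_events.tsv")
                )
        roi_matrices = _glm_patterns(table, patterns, spec, config)
    else:
        roi_matrices = patterns.patterns

    logger.info("stage converge + univariate")
    modeling = analyze_patterns(
        table,
        roi_matrices,
        spec,
        centroid_method=config.centroid_method,
        outlier_threshold_sd=config.outlier_threshold_sd,
    )
    files.append(io.write_trial_table(modeling, outdir / "modeling_table.csv"))

    logger.info("stage model")
    results = _model_stage(modeling, spec, config)

    if config.run_permmap and spec.n_grid_voxels > 0:
        logger.info("stage permmap: %d voxels, %d permutations", spec.n_grid_voxels, config.n_perm)
        summary, coupled, bm = _permmap_stage(table, modeling, spec, config)
        results["permmap"] = summary
        permdf = pd.DataFrame(
            {
                "voxel": np.arange(bm.group_t.size),
                "group_t": bm.group_t,
                "group_p": bm.group_p,
                "fwe_mask": bm.fwe_mask.astype(int),
                "planted": np.isin(np.arange(bm.group_t.size), coupled).astype(int),
            }
        )
        files.append(io.write_trial_table(permdf, outdir / "permmap_voxels.csv"))

    files.append(io.write_results_json(results, outdir / "results.json"))
    files.append(_write_report(results, outdir / "report.txt"))
    manifest = io.write_manifest(outdir, config.to_dict(), config.seed, files)
    files.append(manifest)
    return PipelineResult(
        outdir=outdir, trial_table=table, modeling_table=modeling, results=results, files=files
    )


def _write_report(results: dict, path: Path) -> Path:
    lines = ["convstate run report", "=" * 40]
    rc = results.get("recall_contrast")
    if rc:
        lines += [
            "",
            "Behavior: recall %(rate)s, mean diff %(md).3f, t(%(df)d) = %(t).2f, p = %(p).2g, d = %(d).2f"
            % {
                "rate": ", ".join(f"{k} {v:.3f}" for k, v in rc["rate_by_condition"].items()),
                "md": rc["mean_diff"],
                "df": rc["df"],
                "t": rc["t"],
                "p": rc["p"],
                "d": rc["d"],
            },
        ]
    for roi, eff in results.get("condition_effects", {}).items():
        lines.append(
            f"Curiosity -> typicality [{roi}]: b = {eff['b']:.4f}, SE = {eff['se']:.4f}, p = {eff['p']:.3g}"
        )
    if "modulator_typicality" in results:
        eff = results["modulator_typicality"]
        lines.append(
            f"Modulator -> typicality: b = {eff['b']:.4f}, SE = {eff['se']:.4f}, p = {eff['p']:.3g}"
        )
    for term, eff in results.get("memory_model", {}).items():
        lines.append(
            f"Memory model [{term}]: b = {eff['b']:.3f}, SE = {eff['se']:.3f}, p = {eff['p']:.3g}"
        )
    med = results.get("mediation")
    if med:
        lines.append(
            "Mediation: indirect = %.4f, pME = %.3f, CI95 = [%.3f %.3f], p = %.3g"
            % (
                med["indirect"],
                med["prop_mediated"],
                med["ci95_prop"][0],
                med["ci95_prop"][1],
                med["p_indirect"],
            )
        )
    sc = results.get("subject_correlation")
    if sc:
        lines.append(
            "Subject-level modulator/typicality r = %.3f, CI95 = [%.2f %.2f], p = %.3g"
            % (sc["r"], sc["ci95"][0], sc["ci95"][1], sc["p"])
        )
    pm = results.get("permmap")
    if pm:
        lines.append(
            "Permutation map: %(n_fwe_voxels)d FWE voxels (%(n_fwe_in_planted)d in planted region of %(n_coupled_planted)d)"
            % pm
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def measure_cohort(
    spec: CohortSpec,
    rois: list[str] | None = None,
    centroid_method: str = "kmeans_mean",
) -> pd.DataFrame:
    """Pattern-level shortcut: generate a cohort and return its modeling
    table (typicality + univariate features joined to the trial table).

    Used by the calibration and recovery suites where the GLM stage is
    not under test.
    """
    table, patterns = synthetic.generate_cohort(spec, rois=rois)
    return analyze_patterns(table, patterns.patterns, spec, centroid_method=centroid_method)
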