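"""Tests of the synthetic cohort generator: structure, determinism,
planted geometry, and marginal calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from convstate import synthetic as syn
from convstate.config import (
    CohortSpec,
    calibrate_memory_intercept,
    marginal_recall_probability,
)
from convstate.convergence import loro_typicality


class TestTrialTable:
    def test_full_design_row_count(self):
        # 23 subjects x 6 runs x (12 + 12) trials = 3,312 rows
        spec = CohortSpec(seed=0)
        table = syn.generate_trial_table(spec)
        assert len(table) == 3312

    def test_counterbalanced_conditions_per_run(self, small_spec):
        table = syn.generate_trial_table(small_spec)
        counts = table.groupby(["subject_id", "run", "condition"]).size()
        assert (counts == small_spec.trials_per_condition_per_run).all()

    def test_onsets_increase_and_delays_from_menu(self, small_spec):
        table = syn.generate_trial_table(small_spec)
        for _, g in table.groupby(["subject_id", "run"]):
            onsets = g.sort_values("trial_in_run")["onset_question_s"].to_numpy()
            assert np.all(np.diff(onsets) > 0)
        assert set(table["delay_s"]) <= set(small_spec.anticipation_delays_s)
        np.testing.assert_allclose(
            table["onset_answer_s"], table["onset_question_s"] + table["delay_s"]
        )

    def test_degenerate_generator_constant_eccentricity(self):
        spec = CohortSpec(
            n_subjects=2,
            n_runs=2,
            trials_per_condition_per_run=3,
            eccentricity_condition_shift=0.0,
            modulator_typicality_slope=0.0,
            eccentricity_noise_sd=0.0,
            subject_eccentricity_sd=0.0,
            seed=1,
        )
        table = syn.generate_trial_table(spec)
        np.testing.assert_allclose(
            table["latent_eccentricity"], spec.eccentricity_base, atol=1e-12
        )

    def test_determinism_byte_identical_serialization(self, small_spec):
        t1 = syn.generate_memory_outcomes(syn.generate_trial_table(small_spec), small_spec)
        t2 = syn.generate_memory_outcomes(syn.generate_trial_table(small_spec), small_spec)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="positive integer"):
            CohortSpec(n_subjects=0)
        with pytest.raises(ValueError, match="positive integer"):
            CohortSpec(n_runs=-1)


class TestMemoryOutcomes:
    def test_marginal_calibration_at_zero_slopes(self):
        # at zero slopes and no subject heterogeneity, realized recall per
        # condition must fall in the binomial 99% CI of the intercepts'
        # implied probabilities
        spec = CohortSpec(
            memory_typicality_slope=0.0,
            memory_modulator_slope=0.0,
            memory_subject_sd=0.0,
            seed=5,
        )
        table = syn.generate_memory_outcomes(syn.generate_trial_table(spec), spec)
        for cond, p_target in (("high", None), ("low", None)):
            mu = spec.memory_intercept_by_condition[cond]
            p_implied = marginal_recall_probability(mu, 0.0)
            sub = table[table["condition"] == cond]
            n = len(sub)
            lo, hi = stats.binom.interval(0.99, n, p_implied)
            assert lo <= sub["recalled"].sum() <= hi

    def test_intercepts_imply_study_recall_rates(self):
        spec = CohortSpec()
        for cond, target in (("high", 0.63), ("low", 0.40)):
            mu = spec.memory_intercept_by_condition[cond]
            assert marginal_recall_probability(mu, spec.memory_subject_sd) == pytest.approx(
                target, abs=1e-9
            )
        # the calibration inverts the marginalization
        assert calibrate_memory_intercept(0.5, 1.3) == pytest.approx(0.0, abs=1e-9)

    def test_logistic_saturation_with_extreme_slope(self, small_spec):
        spec = small_spec.replace(memory_typicality_slope=-1e4, seed=2)
        table = syn.generate_memory_outcomes(syn.generate_trial_table(spec), spec)
        # positive eccentricities + hugely negative slope -> nobody recalls
        assert table["recalled"].sum() == 0

    def test_planted_slope_recovered_from_latents(self):
        # oracle: a plain logistic fit on the generator's own latent
        # columns recovers the planted log-odds slope within sampling error
        import statsmodels.api as sm

        spec = CohortSpec(memory_modulator_slope=0.0, memory_subject_sd=0.0, seed=3)
        table = syn.generate_memory_outcomes(syn.generate_trial_table(spec), spec)
        X = pd.DataFrame(
            {
                "const": 1.0,
                "ecc": table["latent_eccentricity"],
                "cond": (table["condition"] == "high").astype(float),
            }
        )
        fit = sm.GLM(table["recalled"], X, family=sm.families.Binomial()).fit()
        assert fit.params["ecc"] == pytest.approx(
            spec.memory_typicality_slope, abs=3 * fit.bse["ecc"]
        )


class TestPatterns:
    def test_noise_free_zero_eccentricity_rows_equal_prototype(self):
        spec = CohortSpec(
            n_subjects=2,
            n_runs=2,
            trials_per_condition_per_run=3,
            n_voxels_by_roi={"HPC": 30},
            eccentricity_base=0.0,
            eccentricity_condition_shift=0.0,
            modulator_typicality_slope=0.0,
            eccentricity_noise_sd=0.0,
            subject_eccentricity_sd=0.0,
            pattern_noise_sd=0.0,
            modulator_roi="VTA",
            seed=4,
        )
        table = syn.generate_trial_table(spec)
        pats = syn.generate_patterns(table, spec)
        for si, subj in enumerate(pats.subjects):
            rows = pats.subject_rows(table, subj)
            np.testing.assert_allclose(
                pats.patterns["HPC"][rows],
                np.tile(pats.prototypes["HPC"][si], (len(rows), 1)),
                atol=1e-10,
            )

    def test_noise_free_distance_equals_planted_eccentricity(self):
        # the geometry is constructed so that, without voxel noise, the
        # correlation distance from the prototype IS the latent scalar
        spec = CohortSpec(
            n_subjects=1,
            n_runs=3,
            trials_per_condition_per_run=8,
            n_voxels_by_roi={"HPC": 200},
            pattern_noise_sd=0.0,
            seed=6,
        )
        table = syn.generate_trial_table(spec)
        pats = syn.generate_patterns(table, spec)
        proto = pats.prototypes["HPC"][0]
        from convstate.convergence import correlation_distance

        for i in range(len(table)):
            d = correlation_distance(pats.patterns["HPC"][i], proto)
            assert d == pytest.approx(table["latent_eccentricity"][i], abs=1e-9)

    def test_two_eccentricity_levels_strictly_ordered(self, rng):
        spec = CohortSpec(
            n_subjects=1,
            n_runs=2,
            trials_per_condition_per_run=10,
            n_voxels_by_roi={"HPC": 100},
            eccentricity_base=0.2,
            eccentricity_condition_shift=0.3,  # high gets 0.5, low 0.2
            modulator_typicality_slope=0.0,
            eccentricity_noise_sd=0.0,
            subject_eccentricity_sd=0.0,
            pattern_noise_sd=0.0,
            seed=7,
        )
        table = syn.generate_trial_table(spec)
        pats = syn.generate_patterns(table, spec)
        proto = pats.prototypes["HPC"][0]
        from convstate.convergence import correlation_distance

        d = np.array(
            [correlation_distance(p, proto) for p in pats.patterns["HPC"]]
        )
        hi = table["condition"] == "high"
        assert d[hi].mean() > d[~hi].mean()
        assert d[hi].min() > d[~hi].max()

    def test_planted_monotonicity_noise_free_spearman_one(self):
        spec = CohortSpec(
            n_subjects=2,
            n_runs=3,
            trials_per_condition_per_run=6,
            n_voxels_by_roi={"HPC": 80},
            pattern_noise_sd=0.0,
            seed=8,
        )
        from convstate.convergence import correlation_distance

        table = syn.generate_trial_table(spec)
        pats = syn.generate_patterns(table, spec)
        for si, subj in enumerate(pats.subjects):
            rows = pats.subject_rows(table, subj)
            ecc = table["latent_eccentricity"].to_numpy()[rows]
            d_proto = np.array(
                [
                    correlation_distance(pats.patterns["HPC"][i], pats.prototypes["HPC"][si])
                    for i in rows
                ]
            )
            assert stats.spearmanr(d_proto, ecc).statistic == pytest.approx(1.0, abs=1e-12)
            # against the estimated held-out centroid the ordering is
            # preserved up to centroid estimation error
            tt, _ = loro_typicality(
                pats.patterns["HPC"][rows], table["run"].to_numpy()[rows]
            )
            assert stats.spearmanr(tt["distance"], ecc).statistic > 0.95

    def test_pattern_shape_bookkeeping(self, small_spec):
        table = syn.generate_trial_table(small_spec)
        pats = syn.generate_patterns(table, small_spec, rois=["HPC"])
        assert pats.patterns["HPC"].shape == (len(table), 40)

    def test_too_few_voxels_rejected(self, small_spec):
        spec = small_spec.replace(n_voxels_by_roi={"HPC": 2})
        table = syn.generate_trial_table(spec)
        with pytest.raises(ValueError, match="at least 3"):
            syn.generate_patterns(table, spec)

    def test_determinism_bit_identical(self, small_spec):
        table = syn.generate_trial_table(small_spec)
        p1 = syn.generate_patterns(table, small_spec, rois=["HPC"])
        p2 = syn.generate_patterns(table, small_spec, rois=["HPC"])
        np.testing.assert_array_equal(p1.patterns["HPC"], p2.patterns["HPC"])


class TestGrid:
    def test_null_grid_uncorrelated_and_coupled_region_coupled(self, small_spec):
        table = syn.generate_trial_table(small_spec)
        grid, coupled = syn.generate_grid(table, small_spec)
        assert grid.shape == (len(table), small_spec.n_grid_voxels)
        ecc = table["latent_eccentricity"].to_numpy()
        r_coupled = np.mean(
            [stats.pearsonr(grid[:, j], ecc).statistic for j in coupled]
        )
        null_idx = np.arange(small_spec.n_coupled_voxels, small_spec.n_grid_voxels)
        r_null = np.mean(
            [stats.pearsonr(grid[:, j], ecc).statistic for j in null_idx[:50]]
        )
        assert r_coupled > 0.2
        assert abs(r_null) < 0.1
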