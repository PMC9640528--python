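"""Tests of the linking models: behavioral contrast, mixed-model effects,
likelihood-ratio selection, mediation, and subject-level correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from convstate import inference
from convstate.config import CohortSpec
from convstate.glmm import fit_logistic_mixed
from convstate.pipeline import measure_cohort
from convstate import synthetic as syn


def _trials_from_rates(rates: dict[str, dict[str, float]], n_per=10) -> pd.DataFrame:
    rows = []
    for subj, by_cond in rates.items():
        for cond, rate in by_cond.items():
            k = int(round(rate * n_per))
            for i in range(n_per):
                rows.append(
                    {
                        "subject_id": subj,
                        "condition": cond,
                        "recalled": 1 if i < k else 0,
                    }
                )
    return pd.DataFrame(rows)


class TestRecallContrast:
    def test_identical_rates_give_zero_t_and_d(self):
        trials = _trials_from_rates(
            {"a": {"high": 0.5, "low": 0.5}, "b": {"high": 0.3, "low": 0.3}}
        )
        rc = inference.recall_contrast(trials)
        assert rc.t == 0.0 and rc.d == 0.0 and rc.p == 1.0

    def test_hand_computed_paired_t(self):
        # diffs (0.2, 0.3): mean 0.25, sd 0.0707, se 0.05 -> t = 5, df = 1
        trials = _trials_from_rates(
            {"a": {"high": 0.5, "low": 0.3}, "b": {"high": 0.6, "low": 0.3}}
        )
        rc = inference.recall_contrast(trials)
        assert rc.mean_diff == pytest.approx(0.25, abs=1e-12)
        assert rc.t == pytest.approx(5.0, abs=1e-9)
        assert rc.df == 1
        assert rc.d == pytest.approx(0.25 / np.std([0.2, 0.3], ddof=1), abs=1e-9)

    def test_subject_missing_condition_excluded_with_warning(self):
        trials = _trials_from_rates(
            {"a": {"high": 0.5, "low": 0.3}, "b": {"high": 0.6, "low": 0.2}}
        )
        only_high = _trials_from_rates({"c": {"high": 0.4}})
        with pytest.warns(UserWarning, match="excluded 1 subject"):
            rc = inference.recall_contrast(pd.concat([trials, only_high]))
        assert rc.n_subjects == 2


class TestConditionEffect:
    def test_constant_response_gives_null_effect(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(
            {
                "subject_id": np.repeat(list("abcd"), 20),
                "condition": np.tile(["high", "low"], 40),
                "y": np.ones(80) + 1e-9 * rng.standard_normal(80),
            }
        )
        eff = inference.fit_condition_effect(d, "y", random_slopes="never")
        assert abs(eff.b) < 1e-6
        assert eff.p > 0.05  # indistinguishable from no effect
        assert eff.ci95[0] <= 0 <= eff.ci95[1]

    def test_matches_two_stage_estimator_on_balanced_design(self):
        # oracle: per-subject condition means -> paired t; on a balanced
        # design the mixed-model estimate agrees within 1 SE
        spec = CohortSpec(seed=21)
        m = measure_cohort(spec, rois=["HPC"])
        eff = inference.fit_condition_effect(m, "dist_HPC", random_slopes="never")
        means = m.groupby(["subject_id", "condition"])["dist_HPC"].mean().unstack()
        two_stage = float((means["high"] - means["low"]).mean())
        assert eff.b == pytest.approx(two_stage, abs=eff.se)

    def test_single_condition_rejected(self):
        d = pd.DataFrame(
            {"subject_id": ["a"] * 4, "condition": ["high"] * 4, "y": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="both conditions"):
            inference.fit_condition_effect(d, "y")


class TestLrt:
    def test_identical_models_give_zero_chi2(self):
        class Fit:
            def __init__(self, llf, n_params, n_obs=100):
                self.llf, self.n_params, self.n_obs = llf, n_params, n_obs

        cmp = inference.lrt_select(Fit(-50.0, 3), Fit(-50.0, 4))
        assert cmp.chi2 == 0.0 and cmp.p == 1.0 and cmp.preferred == "without"

    def test_chi2_matches_loglik_difference(self):
        rng = np.random.default_rng(5)
        n = 1200
        subj = np.repeat(np.arange(12), 100)
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(0.2 + 0.4 * x)))).astype(float)
        X0 = pd.DataFrame({"const": np.ones(n)})
        X1 = pd.DataFrame({"const": 1.0, "x": x})
        r0 = fit_logistic_mixed(y, X0, subj, se=False)
        r1 = fit_logistic_mixed(y, X1, subj, se=False)
        cmp = inference.lrt_select(r0, r1)
        assert cmp.chi2 == pytest.approx(2 * (r1.llf - r0.llf), abs=1e-8)
        assert cmp.df_diff == 1

    def test_row_mismatch_rejected(self):
        class Fit:
            def __init__(self, llf, n_params, n_obs):
                self.llf, self.n_params, self.n_obs = llf, n_params, n_obs

        with pytest.raises(ValueError, match="different row counts"):
            inference.lrt_select(Fit(-10, 2, 100), Fit(-9, 3, 99))

    def test_random_slope_preferred_when_heterogeneity_planted(self):
        # generator truth: subject-varying typicality->memory slope
        prefer = 0
        n_seeds = 8
        for s in range(n_seeds):
            spec = CohortSpec(memory_typicality_slope_subject_sd=2.0, seed=600 + s)
            t = syn.generate_memory_outcomes(syn.generate_trial_table(spec), spec)
            X = pd.DataFrame(
                {
                    "const": 1.0,
                    "ecc": t["latent_eccentricity"],
                    "cond": (t["condition"] == "high").astype(float),
                }
            )
            y = t["recalled"].to_numpy(float)
            g = t["subject_id"].to_numpy()
            r0 = fit_logistic_mixed(y, X, g, se=False)
            r1 = fit_logistic_mixed(y, X, g, slope_col="ecc", se=False)
            cmp = inference.lrt_select(r0, r1, labels=("ri", "rs"))
            prefer += cmp.preferred == "rs"
        assert prefer >= n_seeds - 1


class TestMemoryModel:
    def test_planted_slope_recovered_from_measured_typicality(self):
        spec = CohortSpec(seed=31)
        m = measure_cohort(spec, rois=["VTA", "HPC"])
        m = m.assign(cond_high=(m["condition"] == "high").astype(float))
        effects, _ = inference.fit_memory_model(
            m, ["dist_HPC", "uni_VTA", "cond_high"]
        )
        eff = {e.term: e for e in effects}["dist_HPC"]
        assert eff.b < 0
        assert eff.b == pytest.approx(spec.memory_typicality_slope, abs=3 * eff.se)

    def test_outlier_exclusion_changes_estimate_little(self):
        # the robustness check: refit after excluding flagged outliers
        spec = CohortSpec(seed=32)
        m = measure_cohort(spec, rois=["HPC"])
        eff_all = inference.fit_condition_effect(m, "dist_HPC", random_slopes="never")
        kept = m[m["outlier_flag"] == 0]
        assert len(kept) < len(m)
        eff_kept = inference.fit_condition_effect(kept, "dist_HPC", random_slopes="never")
        assert eff_kept.b == pytest.approx(eff_all.b, rel=0.10)

    def test_interaction_form_supported(self):
        spec = CohortSpec(seed=33)
        m = measure_cohort(spec, rois=["HPC"])
        m = m.assign(cond_high=(m["condition"] == "high").astype(float))
        effects, _ = inference.fit_memory_model(
            m, ["dist_HPC", "cond_high"], interactions=[("dist_HPC", "cond_high")]
        )
        assert {e.term for e in effects} == {
            "dist_HPC",
            "cond_high",
            "dist_HPC:cond_high",
        }


class TestMediation:
    def test_single_boot_with_fixed_seed_is_deterministic(self):
        spec = CohortSpec(seed=41, n_subjects=6, n_runs=2, trials_per_condition_per_run=6)
        m = measure_cohort(spec, rois=["VTA", "HPC"])
        r1 = inference.mediate(m, "uni_VTA", "dist_HPC", n_boot=1, seed=9)
        r2 = inference.mediate(m, "uni_VTA", "dist_HPC", n_boot=1, seed=9)
        assert r1 == r2

    def test_point_estimates_match_statsmodels_fits(self):
        import statsmodels.api as sm

        spec = CohortSpec(seed=42, n_subjects=8, n_runs=3)
        m = measure_cohort(spec, rois=["VTA", "HPC"])
        res = inference.mediate(m, "uni_VTA", "dist_HPC", n_boot=1, seed=0)
        a = np.polyfit(m["uni_VTA"], m["dist_HPC"], 1)[0]
        X = sm.add_constant(m[["uni_VTA", "dist_HPC"]])
        fit = sm.GLM(m["recalled"], X, family=sm.families.Binomial()).fit()
        assert res.indirect == pytest.approx(a * fit.params["dist_HPC"], abs=1e-8)
        assert res.direct == pytest.approx(fit.params["uni_VTA"], abs=1e-8)


class TestSubjectCorrelation:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert inference.subject_correlation(x, x).r == pytest.approx(1.0)
        assert inference.subject_correlation(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            inference.subject_correlation(np.ones(5), np.arange(5.0))

    def test_sampling_distribution_around_planted_coupling(self):
        # oracle: the sampling distribution of r at n = 23, rho = -0.6
        rng = np.random.default_rng(99)
        rho = -0.6
        cov = [[1, rho], [rho, 1]]
        rs = []
        for _ in range(100):
            xy = rng.multivariate_normal([0, 0], cov, size=23)
            rs.append(inference.subject_correlation(xy[:, 0], xy[:, 1]).r)
        assert -0.75 < np.mean(rs) < -0.45

    def test_ci_and_p_match_scipy(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal((2, 23))
        sc = inference.subject_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert sc.r == pytest.approx(ref.statistic)
        assert sc.p == pytest.approx(ref.pvalue)
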