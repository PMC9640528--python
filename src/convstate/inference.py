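"""Linking models: condition effects, subsequent-memory models, model
comparison, mediation, and subject-level correlations.

All trial-level models respect the repeated-measures structure: linear
responses use a subject random-intercept mixed model (statsmodels MixedLM,
ML estimation so nested fits support likelihood-ratio tests), binary
recall uses the adaptive-quadrature logistic mixed model in
:mod:`convstate.glmm`.  Random slopes for a focal predictor are attempted
and retained when a likelihood-ratio test prefers them at p < 0.05.

Mediation uses a nonparametric bootstrap over subjects: subjects are
resampled with replacement, the mediator model (OLS) and outcome model
(logistic) are refit on each resample, and the indirect effect is the
product of the treatment->mediator and mediator->outcome coefficients on
the linear-predictor scale, with percentile confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .glmm import LogisticMixedResult, fit_logistic_mixed

__all__ = [
    "FixedEffect",
    "RecallContrast",
    "ModelComparison",
    "MediationResult",
    "SubjectCorrelation",
    "recall_contrast",
    "fit_condition_effect",
    "fit_continuous_effect",
    "fit_memory_model",
    "fit_time_on_task",
    "lrt_select",
    "mediate",
    "subject_correlation",
]

logger = logging.getLogger(__name__)

_Z975 = stats.norm.ppf(0.975)


@dataclass
class FixedEffect:
    term: str
    b: float
    se: float
    p: float
    ci95: tuple[float, float]


@dataclass
class RecallContrast:
    """Paired contrast of per-subject recall rates between conditions."""

    mean_diff: float
    t: float
    df: int
    p: float
    d: float
    ci95: tuple[float, float]
    rate_by_condition: dict[str, float]
    n_subjects: int


@dataclass
class ModelComparison:
    chi2: float
    df_diff: int
    p: float
    preferred: str


@dataclass
class MediationResult:
    indirect: float
    direct: float
    total: float
    prop_mediated: float
    ci95_indirect: tuple[float, float]
    ci95_prop: tuple[float, float]
    p_indirect: float
    n_boot: int
    seed: int
    stable_total: bool = True


@dataclass
class SubjectCorrelation:
    r: float
    ci95: tuple[float, float]
    p: float
    n: int


# --------------------------------------------------------------------------
# behavioral contrast


def recall_contrast(
    trials: pd.DataFrame,
    conditions: tuple[str, str] = ("high", "low"),
) -> RecallContrast:
    """Paired two-tailed t-test on per-subject recall rates (first minus
    second condition), with Cohen's d = mean difference / SD of differences.

    Subjects missing either condition are excluded with a warning.
    """
    rates = (
        trials.groupby(["subject_id", "condition"], sort=False)["recalled"]
        .mean()
        .unstack("condition")
    )
    complete = rates.dropna(subset=list(conditions))
    dropped = len(rates) - len(complete)
    if dropped:
        warnings.warn(f"excluded {dropped} subject(s) missing a condition")
    if len(complete) < 2:
        raise ValueError("need at least 2 subjects with both conditions")
    a = complete[conditions[0]].to_numpy()
    b = complete[conditions[1]].to_numpy()
    diffs = a - b
    n = len(diffs)
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        t_val, p = 0.0, 1.0
        d = 0.0
        ci = (mean_diff, mean_diff)
    else:
        se = sd / np.sqrt(n)
        t_val = mean_diff / se
        p = float(2 * stats.t.sf(abs(t_val), n - 1))
        d = mean_diff / sd
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    return RecallContrast(
        mean_diff=mean_diff,
        t=float(t_val),
        df=n - 1,
        p=p,
        d=float(d),
        ci95=(float(ci[0]), float(ci[1])),
        rate_by_condition={c: float(complete[c].mean()) for c in conditions},
        n_subjects=n,
    )


# --------------------------------------------------------------------------
# linear mixed models


def _mixedlm_effect(res, term: str) -> FixedEffect:
    b = float(res.params[term])
    se = float(res.bse[term])
    p = float(res.pvalues[term])
    return FixedEffect(term=term, b=b, se=se, p=p, ci95=(b - _Z975 * se, b + _Z975 * se))


def _fit_mixedlm(data: pd.DataFrame, response: str, fixed: list[str], re_formula=None):
    endog = data[response].to_numpy(float)
    exog = sm.add_constant(data[fixed].to_numpy(float), has_constant="add")
    names = ["const"] + fixed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            endog,
            pd.DataFrame(exog, columns=names),
            groups=data["subject_id"].to_numpy(),
            exog_re=(
                pd.DataFrame(exog, columns=names)[re_formula]
                if re_formula is not None
                else None
            ),
        )
        errors = []
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                return model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                errors.append(f"{method}: {exc}")
    raise RuntimeError(
        "mixed model failed to converge with any optimizer "
        f"(fallback chain exhausted): {errors}"
    )


def _n_params(res) -> int:
    """Number of free parameters of a fitted model (for LRTs)."""
    if hasattr(res, "n_params"):
        return int(res.n_params)
    if hasattr(res, "k_fe"):  # MixedLMResults
        k_re = res.model.exog_re.shape[1] if res.model.exog_re is not None else 1
        return int(res.k_fe) + k_re * (k_re + 1) // 2 + 1  # + residual variance
    return int(len(res.params))


def fit_condition_effect(
    data: pd.DataFrame,
    response: str,
    condition_col: str = "condition",
    high_label: str = "high",
    random_slopes: str = "auto",
) -> FixedEffect:
    """Condition (high vs low) effect on a trial-level response.

    Linear mixed model with subject random intercepts; the condition is
    coded 1 for ``high_label`` so the estimate is high-minus-low.  A
    random slope for condition is attempted under the ``auto`` policy and
    retained when an LRT prefers it at p < 0.05.
    """
    d = data.copy()
    d["_cond"] = (d[condition_col] == high_label).astype(float)
    if d["_cond"].nunique() < 2:
        raise ValueError("both conditions must be present")
    return fit_continuous_effect(d, response, "_cond", random_slopes=random_slopes, term_name=f"{condition_col}[{high_label}]")


def fit_continuous_effect(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    random_slopes: str = "auto",
    term_name: str | None = None,
) -> FixedEffect:
    """Trial-level slope of ``response`` on ``predictor`` (linear mixed model).

    Used both for the curiosity->typicality contrast (with a coded
    condition column) and for the modulator->typicality model.
    """
    res0 = _fit_mixedlm(data, response, [predictor])
    res = res0
    if random_slopes in ("auto", "always"):
        try:
            res1 = _fit_mixedlm(data, response, [predictor], re_formula=["const", predictor])
            if random_slopes == "always":
                res = res1
            else:
                cmp = lrt_select(res0, res1, labels=("intercept_only", "random_slope"))
                if cmp.preferred == "random_slope":
                    res = res1
        except Exception as exc:  # slope model may fail to converge
            logger.warning("random-slope fit failed (%s); using intercept-only", exc)
    eff = _mixedlm_effect(res, predictor)
    if term_name:
        eff.term = term_name
    return eff


def fit_time_on_task(
    typicality: pd.DataFrame, response: str = "distance"
) -> list[FixedEffect]:
    """Run number, within-run trial number and their interaction as
    predictors of pattern typicality (time-on-task control model)."""
    d = typicality.copy()
    d["_run"] = d["run"].astype(float) - d["run"].astype(float).mean()
    d["_trial"] = d["trial_in_run"].astype(float) - d["trial_in_run"].astype(float).mean()
    d["_run_x_trial"] = d["_run"] * d["_trial"]
    res = _fit_mixedlm(d, response, ["_run", "_trial", "_run_x_trial"])
    return [_mixedlm_effect(res, t) for t in ("_run", "_trial", "_run_x_trial")]


# --------------------------------------------------------------------------
# mixed-effects logistic subsequent-memory model


def fit_memory_model(
    data: pd.DataFrame,
    predictors: list[str],
    outcome: str = "recalled",
    interactions: list[tuple[str, str]] | None = None,
    random_slopes: str = "never",
    focal: str | None = None,
    exclude_outliers: bool = False,
) -> tuple[list[FixedEffect], LogisticMixedResult]:
    """Mixed-effects logistic regression of recall on trial-level brain
    measures, all predictors entered jointly, subject random intercepts.

    ``interactions`` adds product terms; ``random_slopes='auto'`` attempts
    a random slope for the ``focal`` predictor and keeps it when an LRT
    prefers it.  ``exclude_outliers`` drops rows with a nonzero
    ``outlier_flag`` column when present.
    """
    d = data
    if exclude_outliers and "outlier_flag" in d.columns:
        d = d[d["outlier_flag"] == 0]
    y = d[outcome].to_numpy(float)
    if np.unique(y).size < 2:
        raise ValueError("outcome is degenerate in this cohort")
    X = pd.DataFrame({"const": np.ones(len(d))})
    for pcol in predictors:
        X[pcol] = d[pcol].to_numpy(float)
    for a, b in interactions or []:
        X[f"{a}:{b}"] = d[a].to_numpy(float) * d[b].to_numpy(float)
    groups = d["subject_id"].to_numpy()
    res0 = fit_logistic_mixed(y, X, groups)
    res = res0
    if random_slopes in ("auto", "always"):
        if focal is None:
            raise ValueError("random_slopes policy needs a focal predictor")
        res1 = fit_logistic_mixed(y, X, groups, slope_col=focal)
        if random_slopes == "always":
            res = res1
        else:
            cmp = lrt_select(res0, res1, labels=("intercept_only", "random_slope"))
            if cmp.preferred == "random_slope":
                res = res1
    effects = [
        FixedEffect(
            term=t,
            b=float(res.params[t]),
            se=float(res.bse[t]),
            p=float(res.pvalues[t]),
            ci95=(float(res.conf_int.loc[t, "lower"]), float(res.conf_int.loc[t, "upper"])),
        )
        for t in X.columns
        if t != "const"
    ]
    return effects, res


def lrt_select(model_without, model_with, labels=("without", "with")) -> ModelComparison:
    """Likelihood-ratio test between two nested fits.

    chi2 = 2 (ll_with - ll_without), df = parameter-count difference, p
    from the chi-square tail; the richer model is preferred at p < 0.05.
    Both fits must be on the same rows (checked via stored n_obs when
    available).
    """
    ll0 = float(getattr(model_without, "llf"))
    ll1 = float(getattr(model_with, "llf"))
    n0 = getattr(model_without, "n_obs", getattr(model_without, "nobs", None))
    n1 = getattr(model_with, "n_obs", getattr(model_with, "nobs", None))
    if n0 is not None and n1 is not None and int(n0) != int(n1):
        raise ValueError(f"models fit on different row counts ({n0} vs {n1})")
    df_diff = _n_params(model_with) - _n_params(model_without)
    if df_diff <= 0:
        raise ValueError("model_with must have more parameters than model_without")
    chi2 = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(chi2, df_diff))
    return ModelComparison(
        chi2=chi2, df_diff=df_diff, p=p, preferred=labels[1] if p < 0.05 else labels[0]
    )


# --------------------------------------------------------------------------
# mediation (cluster bootstrap over subjects)


def _weighted_ols_slope(x, y, w):
    """Slope of y ~ 1 + x with per-row weights, vectorized over boot axis.

    x, y: (n,); w: (B, n).  Returns (B,) slopes."""
    sw = w.sum(axis=1)
    mx = (w @ x) / sw
    my = (w @ y) / sw
    cov = (w @ (x * y)) / sw - mx * my
    var = (w @ (x * x)) / sw - mx**2
    return cov / var


def _weighted_logistic(X, y, w, maxiter=30, tol=1e-10):
    """Weighted logistic regression, vectorized over the boot axis.

    X: (n, p); y: (n,); w: (B, n) nonnegative weights.  Returns (B, p)
    coefficient matrix (IRLS / Newton, shared design)."""
    B, n = w.shape
    p = X.shape[1]
    beta = np.zeros((B, p))
    for _ in range(maxiter):
        eta = np.clip(beta @ X.T, -30, 30)  # (B, n)
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = ((w * (y[None, :] - mu))[:, :, None] * X[None, :, :]).sum(axis=1)  # (B,p)
        wr = w * mu * (1 - mu)  # (B, n)
        H = np.einsum("bn,np,nq->bpq", wr, X, X)
        H[:, np.arange(p), np.arange(p)] += 1e-10
        step = np.linalg.solve(H, g[..., None])[..., 0]
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


def mediate(
    data: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str = "recalled",
    n_boot: int = 5000,
    seed: int = 0,
    chunk: int = 512,
) -> MediationResult:
    """Mediation of the treatment->outcome path by the mediator.

    Point estimates come from the full sample: ``a`` is the OLS slope of
    mediator on treatment, ``b`` and the direct effect ``c'`` come from a
    logistic regression of the outcome on treatment + mediator.  The
    indirect effect is a*b on the linear-predictor (log-odds) scale, the
    total effect is c' + a*b, and pME = indirect / total (this additive
    decomposition is exact for a linear mediator model and an
    approximation on the log-odds scale for the binary outcome).

    Uncertainty comes from a nonparametric bootstrap that resamples
    SUBJECTS with replacement (a resampled subject's trials enter with
    its multiplicity, implemented as weighted refits), giving percentile
    95% CIs and a two-sided bootstrap p for the indirect effect.
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    t = data[treatment].to_numpy(float)
    m = data[mediator].to_numpy(float)
    y = data[outcome].to_numpy(float)
    subjects = data["subject_id"].to_numpy()
    uniq, subj_idx = np.unique(subjects, return_inverse=True)
    G = len(uniq)
    X_out = np.column_stack([np.ones_like(t), t, m])

    def _estimates(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = _weighted_ols_slope(t, m, w)
        beta = _weighted_logistic(X_out, y, w)
        return a, beta[:, 2], beta[:, 1]  # a, b, c'

    a0, b0, c0 = (v[0] for v in _estimates(np.ones((1, len(t)))))
    indirect0 = float(a0 * b0)
    direct0 = float(c0)
    total0 = indirect0 + direct0

    rng = np.random.default_rng(seed)
    draws_ind = np.empty(n_boot)
    draws_dir = np.empty(n_boot)
    for start in range(0, n_boot, chunk):
        bsize = min(chunk, n_boot - start)
        picks = rng.integers(0, G, size=(bsize, G))
        counts = np.zeros((bsize, G))
        for bi in range(bsize):
            counts[bi] = np.bincount(picks[bi], minlength=G)
        w = counts[:, subj_idx]
        a, b, c = _estimates(w)
        draws_ind[start : start + bsize] = a * b
        draws_dir[start : start + bsize] = c
    draws_tot = draws_ind + draws_dir
    ci_ind = tuple(np.quantile(draws_ind, [0.025, 0.975]))
    stable = abs(total0) > 1e-8 and not np.any(np.abs(draws_tot) < 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        draws_prop = draws_ind / draws_tot
    ci_prop = tuple(np.quantile(draws_prop[np.isfinite(draws_prop)], [0.025, 0.975]))
    if not stable:
        warnings.warn("total effect near zero; prop_mediated is unstable")
    n_le = int(np.sum(draws_ind <= 0))
    n_ge = int(np.sum(draws_ind >= 0))
    p_ind = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
    return MediationResult(
        indirect=indirect0,
        direct=direct0,
        total=total0,
        prop_mediated=indirect0 / total0 if total0 != 0 else np.nan,
        ci95_indirect=(float(ci_ind[0]), float(ci_ind[1])),
        ci95_prop=(float(ci_prop[0]), float(ci_prop[1])),
        p_indirect=float(p_ind),
        n_boot=n_boot,
        seed=seed,
        stable_total=stable,
    )


# --------------------------------------------------------------------------
# between-subject correlation


def subject_correlation(x: np.ndarray, y: np.ndarray) -> SubjectCorrelation:
    """Pearson correlation across subjects with Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return SubjectCorrelation(
        r=float(res.statistic), ci95=(float(ci.low), float(ci.high)), p=float(res.pvalue), n=n
    )
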