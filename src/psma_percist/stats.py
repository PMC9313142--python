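"""Inferential layer: ROC cutoffs, mixed models on log SUV, geometric means,
covariate-adjusted logistic screens with likelihood-ratio tests, and survival.

All SUV analyses operate on natural-log transformed values (SUV
distributions are right-skewed); exponentiated coefficients are therefore
multiplicative ratios between response categories.  Mixed models use a
per-patient random intercept to absorb between-patient variation of lesion
uptake, and are fitted by maximum likelihood (not REML) so that
likelihood-ratio tests against nested models are valid.  Significance is
two-sided at alpha = 0.05 with no multiplicity correction (a documented
limitation of the screening design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

IMAGING_LEVELS = ("iPD", "iSD", "iPR", "iCR")  # iPD is the reference level


def format_value(x: float, decimals: int) -> str:
    """Fixed-point formatting used in coefficient reports."""
    return f"{x:.{decimals}f}"


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    cutoff_youden: float
    sens_youden: float
    spec_youden: float
    cutoff_minspec: float
    sens_minspec: float
    spec_minspec: float
    min_spec: float
    thresholds: np.ndarray = field(repr=False, default=None)
    sensitivities: np.ndarray = field(repr=False, default=None)
    specificities: np.ndarray = field(repr=False, default=None)
    auc_bootstrap_corrected: float | None = None


def roc_cutoffs(scores, responder, min_spec: float = 0.80) -> RocResult:
    """Empirical ROC with Youden-index and minimum-specificity cutoffs.

    Convention: higher score predicts responder; a cutoff ``c`` classifies
    ``score >= c`` as responder.  The Youden cutoff maximizes
    sensitivity + specificity - 1 (ties resolved toward higher specificity,
    then the larger cutoff).  The minimum-specificity cutoff is the smallest
    threshold whose specificity reaches ``min_spec``, reported with its
    sensitivity.  AUC is the trapezoidal area (equivalently the concordance
    of the score).
    """
    scores = np.asarray(scores, dtype=float)
    responder = np.asarray(responder, dtype=bool)
    if scores.shape != responder.shape or scores.ndim != 1:
        raise ValueError("scores and responder must be 1-D arrays of equal length")
    if responder.all() or not responder.any():
        raise ValueError("both classes must be present")

    pos = scores[responder]
    neg = scores[~responder]
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    sens = np.array([(pos >= c).mean() for c in thresholds])
    spec = np.array([(neg < c).mean() for c in thresholds])
    j = sens + spec - 1.0

    best = max(range(len(thresholds)), key=lambda i: (j[i], spec[i], thresholds[i]))
    qualifying = np.flatnonzero(spec >= min_spec)
    ms = int(qualifying[0])  # thresholds ascending -> smallest qualifying cutoff

    return RocResult(
        auc=float(roc_auc_score(responder, scores)),
        cutoff_youden=float(thresholds[best]),
        sens_youden=float(sens[best]),
        spec_youden=float(spec[best]),
        cutoff_minspec=float(thresholds[ms]),
        sens_minspec=float(sens[ms]),
        spec_minspec=float(spec[ms]),
        min_spec=min_spec,
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
    )


def _fit_univariate_logistic(scores: np.ndarray, labels: np.ndarray):
    X = sm.add_constant(scores.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(labels.astype(float), X, family=sm.families.Binomial()).fit(
            maxiter=200
        )


def bootstrap_corrected_auc(
    scores,
    responder,
    B: int = 1000,
    seed: int = 0,
    cluster=None,
    max_redraw_factor: int = 10,
) -> tuple[float, float]:
    """Optimism-corrected c-statistic of the univariate logistic model.

    Harrell's procedure: the apparent AUC of the logistic score on the full
    data, minus the mean over ``B`` bootstrap resamples of (AUC of the
    resample-fit model on the resample - its AUC on the original data).
    Resampling is at row level, or at ``cluster`` level (e.g. patients) when
    cluster ids are given.  Single-class resamples are redrawn, with the
    total number of draws capped.  Returns (corrected, apparent).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(responder, dtype=bool)
    rng = np.random.default_rng(seed)

    full = _fit_univariate_logistic(scores, labels)
    apparent = float(roc_auc_score(labels, full.fittedvalues))

    if cluster is not None:
        cluster = np.asarray(cluster)
        groups = {c: np.flatnonzero(cluster == c) for c in np.unique(cluster)}
        group_ids = list(groups)

    optimism = []
    attempts = 0
    while len(optimism) < B and attempts < B * max_redraw_factor:
        attempts += 1
        if cluster is None:
            idx = rng.integers(0, len(scores), size=len(scores))
        else:
            chosen = rng.choice(group_ids, size=len(group_ids), replace=True)
            idx = np.concatenate([groups[c] for c in chosen])
        yb = labels[idx]
        if yb.all() or not yb.any():
            continue
        try:
            boot = _fit_univariate_logistic(scores[idx], yb)
        except np.linalg.LinAlgError:
            continue
        pb = boot.predict(sm.add_constant(scores[idx], has_constant="add"))
        po = boot.predict(sm.add_constant(scores, has_constant="add"))
        optimism.append(roc_auc_score(yb, pb) - roc_auc_score(labels, po))

    if not optimism:
        raise RuntimeError("no usable bootstrap resample was drawn")
    corrected = float(np.clip(apparent - float(np.mean(optimism)), 0.0, 1.0))
    return corrected, apparent


# ---------------------------------------------------------------------------
# Mixed models on log SUV
# ---------------------------------------------------------------------------


@dataclass
class MixedModelResult:
    coefficients: pd.DataFrame  # coef, ci_low, ci_high, exp_*, p per term
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    tau2: float
    sigma2: float

    @property
    def icc(self) -> float:
        """Intra-class correlation tau^2 / (tau^2 + sigma^2)."""
        total = self.tau2 + self.sigma2
        return self.tau2 / total if total > 0 else float("nan")


def _response_term(rows: pd.DataFrame, response: str) -> str:
    values = set(rows[response].dropna().unique())
    if values <= set(IMAGING_LEVELS) and len(values) > 2:
        return f"C({response}, Treatment(reference='iPD'))"
    return f"C({response})"


def _check_full_rank(rows: pd.DataFrame, formula: str) -> None:
    import patsy

    mat = patsy.dmatrix(formula.split("~", 1)[1], rows, return_type="dataframe")
    rank = np.linalg.matrix_rank(mat.to_numpy())
    if rank < mat.shape[1]:
        raise ValueError(
            "singular design matrix; collinear terms among: "
            + ", ".join(mat.columns)
        )


def fit_lmm(
    rows: pd.DataFrame,
    outcome: str = "log_suv_peak",
    response: str = "responder",
    covariates: tuple[str, ...] = ("psma_tv", "site"),
    interaction: bool = False,
    group: str = "patient_id",
) -> MixedModelResult:
    """Linear mixed model of log SUV on response with a patient random intercept.

    ``response`` may be a dichotomous responder flag or the four-level
    imaging category (reference iPD).  ``covariates`` are added as fixed
    confounders (``site`` is treated as categorical); with
    ``interaction=True`` a site-by-response interaction is added.  Fitting is
    by ML so the reported likelihood-ratio test against the model without
    the response terms is valid.  Exponentiated coefficients are the
    multiplicative SUV ratios versus the reference category.
    """
    rows = rows.copy()
    if rows[group].nunique() < 2:
        raise ValueError("at least two patients are required")
    resp_term = _response_term(rows, response)
    terms = [resp_term]
    null_terms = []
    for cov in covariates:
        if rows[cov].dtype == object or str(rows[cov].dtype) == "category":
            if rows[cov].nunique() < 2:
                continue
            t = f"C({cov})"
        else:
            t = cov
        terms.append(t)
        null_terms.append(t)
    if interaction:
        if "site" not in covariates or rows["site"].nunique() < 2:
            raise ValueError("site interaction requires a site covariate with >1 level")
        terms.append(f"{resp_term}:C(site)")
    formula = f"{outcome} ~ " + " + ".join(terms)
    null_formula = f"{outcome} ~ " + (" + ".join(null_terms) if null_terms else "1")
    _check_full_rank(rows, formula)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm(formula, rows, groups=rows[group]).fit(reml=False)
        null = smf.mixedlm(null_formula, rows, groups=rows[group]).fit(reml=False)

    lrt_stat = 2.0 * (full.llf - null.llf)
    lrt_df = len(full.fe_params) - len(null.fe_params)
    lrt_p = float(sps.chi2.sf(max(lrt_stat, 0.0), lrt_df))

    ci = full.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "coef": full.fe_params,
            "ci_low": ci.loc[full.fe_params.index, 0],
            "ci_high": ci.loc[full.fe_params.index, 1],
            "p": full.pvalues[full.fe_params.index],
        }
    )
    table["exp_coef"] = np.exp(table["coef"])
    table["exp_ci_low"] = np.exp(table["ci_low"])
    table["exp_ci_high"] = np.exp(table["ci_high"])

    return MixedModelResult(
        coefficients=table,
        lrt_statistic=float(lrt_stat),
        lrt_df=int(lrt_df),
        lrt_p=lrt_p,
        tau2=float(np.asarray(full.cov_re)[0, 0]),
        sigma2=float(full.scale),
    )


# ---------------------------------------------------------------------------
# Geometric means
# ---------------------------------------------------------------------------


def geometric_means(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group geometric mean with a t-based CI computed on the log scale.

    Groups of size one are reported with NaN CI bounds and flagged
    degenerate.  Non-positive values are rejected (the log is undefined).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if np.any(values <= 0):
        raise ValueError("geometric means require strictly positive values")
    out = []
    for g in pd.unique(groups):
        logs = np.log(values[groups == g])
        n = logs.size
        gm = float(np.exp(logs.mean()))
        if n > 1:
            se = logs.std(ddof=1) / np.sqrt(n)
            tcrit = sps.t.ppf(1 - alpha / 2, n - 1)
            lo, hi = np.exp(logs.mean() - tcrit * se), np.exp(logs.mean() + tcrit * se)
            degenerate = False
        else:
            lo = hi = float("nan")
            degenerate = True
        out.append(
            {
                "group": g,
                "n": n,
                "geometric_mean": gm,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(out).set_index("group")


# ---------------------------------------------------------------------------
# Covariate-adjusted logistic screens
# ---------------------------------------------------------------------------


@dataclass
class LogisticLrtResult:
    variable: str
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    separation: bool


_SEPARATION_COEF = 10.0


def logistic_lrt(
    patients: pd.DataFrame,
    variable: str,
    outcome: str,
    covariate: str = "psma_tv",
) -> LogisticLrtResult:
    """Univariate logistic screen of ``variable`` adjusted for tumor load.

    Fits ``outcome ~ variable + covariate`` and compares it by likelihood
    ratio with ``outcome ~ covariate``.  The odds ratio of ``variable`` is
    reported with a Wald CI.  Quasi-complete separation (diverging
    coefficient) is detected and flagged; the LRT p-value is still reported,
    as the likelihood difference remains well-defined at the boundary.
    """
    y = patients[outcome].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    x = patients[variable].astype(float).to_numpy()
    z = patients[covariate].astype(float).to_numpy()

    X1 = sm.add_constant(np.column_stack([x, z]))
    X0 = sm.add_constant(z)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        full = sm.GLM(y, X1, family=sm.families.Binomial()).fit(maxiter=200)
        null = sm.GLM(y, X0, family=sm.families.Binomial()).fit(maxiter=200)
    sep_warned = any("separation" in str(w.message).lower() for w in caught)

    coef = float(full.params[1])
    separation = sep_warned or abs(coef) > _SEPARATION_COEF
    if not separation and not full.converged:
        raise RuntimeError("logistic fit did not converge")
    ci = full.conf_int()[1]
    stat = 2.0 * (full.llf - null.llf)
    with np.errstate(over="ignore"):
        ci_low, ci_high = float(np.exp(ci[0])), float(np.exp(ci[1]))
    return LogisticLrtResult(
        variable=variable,
        coef=coef,
        odds_ratio=float(np.exp(coef)),
        ci_low=ci_low,
        ci_high=ci_high,
        lrt_statistic=float(stat),
        lrt_df=1,
        lrt_p=float(sps.chi2.sf(max(stat, 0.0), 1)),
        separation=bool(separation),
    )


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalResult:
    km_curves: dict  # group -> DataFrame(time, survival)
    medians: dict  # group -> median OS in months (inf if not reached)
    logrank_statistic: float
    logrank_p: float


def km_logrank(times, events, groups) -> SurvivalResult:
    """Kaplan-Meier curves per group with a two-sided log-rank test.

    Median OS is the first time the survival function drops to 0.5 or
    below; a group whose curve never reaches 0.5 (e.g. all censored) has
    median +inf (not reached).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank needs at least two groups")

    curves, medians = {}, {}
    for g in pd.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        medians[g] = float(kmf.median_survival_time_)
    lr = multivariate_logrank_test(times, groups, events)
    return SurvivalResult(
        km_curves=curves,
        medians=medians,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
    )


@dataclass
class CoxResult:
    table: pd.DataFrame  # per term: coef, hr, ci_low, ci_high, p
    monotone_likelihood: bool


def cox_univariate(times, events, covariate, name: str = "covariate") -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    Categorical covariates are expanded to treatment contrasts against the
    first listed level.  Monotone partial likelihood (e.g. a level with no
    events, or perfect ranking by the covariate) is detected and flagged.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < 1:
        raise ValueError("at least one event is required")

    cov = pd.Series(covariate).reset_index(drop=True)
    if cov.dtype == object or str(cov.dtype) == "category" or cov.dtype == bool:
        if cov.dtype == bool:
            X = pd.DataFrame({name: cov.astype(float)})
        else:
            cat = pd.Categorical(cov)
            X = pd.get_dummies(
                pd.Series(cat, name=name), prefix=name, drop_first=True, dtype=float
            )
    else:
        X = pd.DataFrame({name: cov.astype(float)})

    df = X.copy()
    df["T"] = times
    df["E"] = events.astype(int)
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="T", event_col="E")
    monotone = any(
        "convergence" in str(w.message).lower() or "complete separation" in str(w.message).lower()
        for w in caught
    ) or bool((cph.summary["se(coef)"] > 100).any())

    summary = cph.summary
    table = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "ci_low": summary["exp(coef) lower 95%"],
            "ci_high": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )
    return CoxResult(table=table, monotone_likelihood=monotone)
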