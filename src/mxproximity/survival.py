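"""Cohort survival analysis.

Implements the TCGA-style survival stage: exclusion filtering, Kaplan-Meier
estimation, the log-rank test, univariable Cox regression reported per
interquartile-range (IQR) change, stage-stratified interaction models with
likelihood-ratio tests, bootstrap optimism-corrected concordance, subgroup
expression comparisons with Bonferroni correction, and the linear
interaction model on gene expression.

Conventions (declared, since the source analysis is silent on them): Efron
tie handling for Cox partial likelihood; median-split ties go to "low";
IQR via linear-interpolation quantiles; Harrell's c with risk-score ties
scored 0.5; bootstrap B = 200 by default under a single seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats as sps

from ._errors import (ConvergenceError, DegenerateStatisticError,
                      ValidationError)
from .io import CohortTable

logger = logging.getLogger(__name__)

_Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# cohort filtering and dichotomization
# ---------------------------------------------------------------------------

def filter_tcga_cohort(cohort: CohortTable) -> CohortTable:
    """Apply the cohort exclusion rules.

    Removes patients with negative overall survival, missing OS time or OS
    status, and patients whose stage maps to ``excluded`` (stage 0, I/II
    NOS, unparseable). Per-criterion removal counts are logged. Idempotent.
    """
    df = cohort.df
    bad_os = df["os_months"].isna() | (df["os_months"] < 0)
    bad_status = df["os_event"].isna()
    bad_stage = df["stage_group"].isna() | (df["stage_group"] == "excluded")
    keep = ~(bad_os | bad_status | bad_stage)
    logger.info(
        "cohort filter: removed %d (OS<0 or missing OS), %d (missing status), "
        "%d (excluded stage); %d of %d retained",
        int(bad_os.sum()), int((bad_status & ~bad_os).sum()),
        int((bad_stage & ~bad_os & ~bad_status).sum()),
        int(keep.sum()), len(df),
    )
    if not keep.any():
        raise ValidationError("cohort filter removed every patient")
    return CohortTable(df[keep].reset_index(drop=True), cohort.gene_columns)


def median_split(values) -> np.ndarray:
    """Dichotomize at the sample median: value <= median -> "low", else
    "high" (tie convention: ties sit in the low group)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValidationError("median split needs >= 2 values")
    if np.ptp(x[np.isfinite(x)]) == 0:
        raise DegenerateStatisticError("constant vector: median split undefined")
    med = np.nanmedian(x)
    return np.where(x <= med, "low", "high")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate on the event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float   # inf when the curve never crosses 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects remain at risk through
    their censoring time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not events.any():
        logger.warning("no events: Kaplan-Meier curve is flat at 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    return KMCurve(grid, surv, at_risk, med)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def log_rank(times, events, group_labels) -> LogRankResult:
    """k-sample log-rank test (chi-square, df = k - 1, two-sided)."""
    groups = pd.Series(group_labels)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    if (sizes < 1).any():
        raise ValidationError("every group needs >= 1 subject")
    res = multivariate_logrank_test(np.asarray(times, dtype=float), groups,
                                    np.asarray(events, dtype=bool))
    df = len(sizes) - 1
    return LogRankResult(float(res.test_statistic), df, float(res.p_value))


# ---------------------------------------------------------------------------
# Cox regression, per-IQR reporting
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFitResult:
    """Cox partial-likelihood fit with per-IQR hazard-ratio reporting."""

    coefficients: dict = field(default_factory=dict)   # term -> (beta, se)
    hr_per_iqr: dict = field(default_factory=dict)     # term -> (HR, lo, hi, iqr)
    wald_p: dict = field(default_factory=dict)
    loglik: float = np.nan
    n: int = 0
    n_events: int = 0
    strata: tuple = ()
    quantile_convention: str = "linear-interpolation (type 7)"

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients)


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.quantile(x, [0.25, 0.75])   # linear interpolation (type 7)
    return float(q3 - q1)


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
             strata=None, penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col,
                    strata=strata)
    except (_LLConvergenceError, np.linalg.LinAlgError) as e:
        raise ConvergenceError(f"Cox fit failed to converge: {e}") from e
    return cph


def _result_from_fit(cph: CoxPHFitter, df: pd.DataFrame, terms,
                     strata=()) -> SurvivalFitResult:
    out = SurvivalFitResult(
        loglik=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df[cph.event_col].sum()),
        strata=tuple(strata),
    )
    for term in terms:
        beta = float(cph.params_[term])
        se = float(cph.standard_errors_[term])
        out.coefficients[term] = (beta, se)
        out.wald_p[term] = float(
            2.0 * sps.norm.sf(abs(beta / se))) if se > 0 else np.nan
        iqr = _iqr(df[term].to_numpy(dtype=float))
        out.hr_per_iqr[term] = (
            float(np.exp(beta * iqr)),
            float(np.exp((beta - _Z95 * se) * iqr)),
            float(np.exp((beta + _Z95 * se) * iqr)),
            iqr,
        )
    return out


def cox_per_iqr(times, events, covariate, name: str = "x") -> SurvivalFitResult:
    """Univariable Cox regression with the hazard ratio reported per IQR.

    ``HR_per_IQR = exp(beta * IQR)`` with the 95% CI endpoints transformed
    the same way; the IQR is computed on the analysis sample, making the
    report invariant to affine rescaling of the covariate.
    """
    x = np.asarray(covariate, dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("constant covariate: Cox fit undefined")
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValidationError("no events: Cox fit undefined")
    df = pd.DataFrame({"T": np.asarray(times, dtype=float),
                       "E": events.astype(int), name: x})
    cph = _fit_cox(df, "T", "E")
    return _result_from_fit(cph, df, [name])


def stratified_cox_interaction(
    cohort,
    score_term: str,
    marker_term: str,
    strata_col: str = "stage_group",
    duration_col: str = "os_months",
    event_col: str = "os_event",
):
    """Fit the reduced (main effects) and full (plus score x marker) Cox
    models with stratum-specific baseline hazards.

    Returns ``(full, reduced)`` fit results; the reduced model's marker term
    is the score-adjusted marker effect. The interaction column is named
    ``<score>:<marker>``.
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    for s, grp in df.groupby(strata_col):
        if len(grp) == 0:
            raise ValidationError(f"empty stratum {s!r}")
        if not grp[event_col].astype(bool).any():
            raise ValidationError(f"stratum {s!r} contains no events")
    inter = f"{score_term}:{marker_term}"
    base = df[[duration_col, event_col, score_term, marker_term,
               strata_col]].copy()
    base[event_col] = base[event_col].astype(int)

    cph_red = _fit_cox(base, duration_col, event_col, strata=[strata_col])
    reduced = _result_from_fit(cph_red, base, [score_term, marker_term],
                               strata=(strata_col,))

    full_df = base.copy()
    full_df[inter] = full_df[score_term] * full_df[marker_term]
    cph_full = _fit_cox(full_df, duration_col, event_col, strata=[strata_col])
    full = _result_from_fit(cph_full, full_df,
                            [score_term, marker_term, inter],
                            strata=(strata_col,))
    return full, reduced


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    p_value: float


def lr_test(full: SurvivalFitResult, reduced: SurvivalFitResult) -> LRTestResult:
    """Likelihood-ratio test of nested Cox models."""
    extra = set(full.terms) - set(reduced.terms)
    if set(reduced.terms) - set(full.terms):
        raise ValidationError("reduced model is not nested in the full model")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise ConvergenceError(
            f"full model log-likelihood below reduced ({stat / 2:.6g}); "
            "fits did not converge to the nested optimum")
    stat = max(stat, 0.0)
    df = len(extra)
    if df == 0:
        return LRTestResult(0.0, 0, 1.0)
    return LRTestResult(stat, df, float(sps.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# concordance with bootstrap optimism correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CIndexResult:
    apparent: float
    optimism: float
    corrected: float
    b_used: int
    b_failed: int


def _model_c(cph: CoxPHFitter, df: pd.DataFrame, duration_col, event_col) -> float:
    risk = cph.predict_partial_hazard(df).to_numpy(dtype=float)
    # Harrell's c: concordance of higher risk with shorter survival; ties in
    # the risk score score 0.5 (lifelines' convention).
    return float(concordance_index(df[duration_col], -risk, df[event_col]))


def c_index_optimism(
    cohort,
    model_terms: list[str],
    duration_col: str = "os_months",
    event_col: str = "os_event",
    B: int = 200,
    seed: int = 0,
    penalizer: float = 0.0,
) -> CIndexResult:
    """Harrell's c-index with bootstrap optimism correction.

    Optimism is the mean over ``B`` bootstrap resamples of (c of the model
    refit on the resample, evaluated on the resample) minus (that refit
    model's c on the original data); corrected = apparent - optimism.
    Deterministic given ``seed``. Bootstrap fits that fail to converge are
    skipped and counted.
    """
    if B < 50:
        raise ValidationError("B must be >= 50 for a stable optimism estimate")
    df = (cohort.df if isinstance(cohort, CohortTable) else cohort)[
        [duration_col, event_col, *model_terms]].copy()
    df[event_col] = df[event_col].astype(int)
    if df[event_col].sum() == 0:
        raise ValidationError("no comparable pairs: zero events")

    cph = _fit_cox(df, duration_col, event_col, penalizer=penalizer)
    apparent = _model_c(cph, df, duration_col, event_col)

    rng = np.random.default_rng(seed)
    optimisms = []
    failed = 0
    n = len(df)
    for _ in range(B):
        boot = df.iloc[rng.integers(0, n, n)].reset_index(drop=True)
        try:
            cph_b = _fit_cox(boot, duration_col, event_col,
                             penalizer=penalizer)
        except ConvergenceError:
            failed += 1
            continue
        c_boot = _model_c(cph_b, boot, duration_col, event_col)
        c_orig = _model_c(cph_b, df, duration_col, event_col)
        optimisms.append(c_boot - c_orig)
    if not optimisms:
        raise ConvergenceError("every bootstrap refit failed")
    optimism = float(np.mean(optimisms))
    return CIndexResult(apparent, optimism, apparent - optimism,
                        len(optimisms), failed)


# ---------------------------------------------------------------------------
# subgroup expression tests and linear interaction model
# ---------------------------------------------------------------------------

def subgroup_expression_tests(
    cohort,
    split_col_a: str,
    split_col_b: str,
    response_cols: list[str],
    label_a: str | None = None,
    label_b: str | None = None,
) -> pd.DataFrame:
    """Median-split two genes into four subgroups and compare each response
    gene across all six subgroup pairs with Wilcoxon rank-sum tests.

    P-values are Bonferroni-adjusted for the 6 pairwise comparisons
    (``p_adj = min(1, 6 p)``). Comparisons with a subgroup of size < 2 are
    flagged (NaN p) rather than computed.
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    la = label_a or split_col_a
    lb = label_b or split_col_b
    a = median_split(df[split_col_a])
    b = median_split(df[split_col_b])
    subgroup = np.array(
        [f"{la}_{'hi' if x == 'high' else 'low'}_{lb}_{'hi' if y == 'high' else 'low'}"
         for x, y in zip(a, b)])
    names = sorted(set(subgroup))
    rows = []
    for resp in response_cols:
        vals = df[resp].to_numpy(dtype=float)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                g1 = vals[subgroup == names[i]]
                g2 = vals[subgroup == names[j]]
                if len(g1) < 2 or len(g2) < 2:
                    rows.append({"response": resp, "group1": names[i],
                                 "group2": names[j], "n1": len(g1),
                                 "n2": len(g2), "statistic": np.nan,
                                 "p_raw": np.nan, "p_bonferroni": np.nan,
                                 "flag": "subgroup too small"})
                    continue
                stat, p = sps.mannwhitneyu(g1, g2, alternative="two-sided")
                rows.append({"response": resp, "group1": names[i],
                             "group2": names[j], "n1": len(g1), "n2": len(g2),
                             "statistic": float(stat), "p_raw": float(p),
                             "p_bonferroni": min(1.0, 6.0 * float(p)),
                             "flag": ""})
    return pd.DataFrame(rows)


def linear_interaction(
    cohort,
    response_col: str,
    marker_col: str = "sox10_z",
    cd8_col: str = "cd8a_expr",
) -> tuple[pd.DataFrame, int]:
    """Multivariable linear model of log2 response on the marker z-score,
    log2 CD8 expression, and their product.

    Rows with non-positive response or CD8 expression (log2 undefined) are
    excluded; the exclusion count is returned and logged. Returns a
    coefficient table (coef, se, t, p per term) and the exclusion count.
    """
    import statsmodels.api as sm

    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    resp = df[response_col].to_numpy(dtype=float)
    cd8 = df[cd8_col].to_numpy(dtype=float)
    marker = df[marker_col].to_numpy(dtype=float)
    keep = (resp > 0) & (cd8 > 0) & np.isfinite(marker)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("linear interaction: excluded %d rows with non-positive "
                    "expression", n_excluded)
    y = np.log2(resp[keep])
    x1 = marker[keep]
    x2 = np.log2(cd8[keep])
    X = np.column_stack([np.ones(keep.sum()), x1, x2, x1 * x2])
    if np.linalg.matrix_rank(X) < 4:
        raise ValidationError("collinear predictors: interaction fit undefined")
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame({
        "term": ["intercept", marker_col, f"log2_{cd8_col}", "interaction"],
        "coef": res.params,
        "se": res.bse,
        "t": res.tvalues,
        "p": res.pvalues,
    })
    return table, n_excluded
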