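"""The statistical battery over the admission cohort.

Five analyses, mirroring a dimensional-psychopathology study design:

1. :func:`baseline_table` — group comparison of demographics and medical
   history at the patient level (one-way ANOVA for continuous variables,
   a chi-square homogeneity test for categorical ones; a literal Cochran Q
   for matched binary layouts is exposed separately as :func:`cochran_q`).
2. :func:`rdoc_group_comparison` — per-domain one-way ANOVA across the three
   diagnosis groups, with pairwise pooled-variance t-tests as post hoc
   analysis when the omnibus test rejects at alpha.  Post hoc p-values are
   unadjusted by default (a Bonferroni option exists).
3. :func:`covariate_regression` — OLS of each domain score (in percentage
   points) on age, sex, and Charlson Comorbidity Index.
4. :func:`los_logistic` — per diagnosis group, multiple logistic regression
   of the dichotomized (>3-day) length of stay on the five domain scores
   plus age, CCI, and sex.  ORs are exp(beta) with Wald 95% CIs.
5. :func:`cox_secondary` — per domain, a Cox proportional-hazards model of
   time to discharge (all events observed) adjusted for demographics and
   diagnosis, *without* the other four domains.  Ties use Efron's method.

Domain scores enter every regression multiplied by 100 (percentage points):
with score SDs of roughly 0.04-0.10 on the fraction scale, per-unit-fraction
odds ratios would be uninterpretable; per-point ORs like 1.06 are the natural
reporting unit.  The scaling is configurable via ``scale``.

Sex is coded female=1, male=0.  Diagnosis reference level is depression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.api as sm
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q

from lifelines import CoxPHFitter

from .cohort import DIAGNOSES, FLAG_COLS, CohortTable, los_binary
from .errors import ValidationError

__all__ = [
    "GroupComparisonRow",
    "PosthocResult",
    "RegressionEffect",
    "baseline_table",
    "rdoc_group_comparison",
    "covariate_regression",
    "los_logistic",
    "cox_secondary",
    "cochran_q",
]

logger = logging.getLogger(__name__)

SCORE_SCALE_DEFAULT = 100.0
ALPHA_DEFAULT = 0.05
MAXITER = 100
TOL = 1e-8


@dataclass(frozen=True)
class GroupComparisonRow:
    """One row of a group-comparison table (one variable, all groups)."""

    variable: str
    summaries: dict[str, str]
    test: str  # "anova" | "categorical_homogeneity"
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class PosthocResult:
    """One pairwise post hoc t-test for one domain."""

    domain: str
    pair: tuple[str, str]
    direction: str  # e.g. "depression > schizophrenia"
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class RegressionEffect:
    """One model term's estimate: slope, log-odds, or log-hazard."""

    model_id: str
    outcome: str
    term: str
    estimate: float  # coefficient on the linear-predictor scale
    or_or_hr: float | None  # exp(estimate) for logistic/Cox, None for OLS
    ci_low: float  # 95% CI on the reported scale (exp'd where or_or_hr is set)
    ci_high: float
    p_value: float
    n_used: int
    flag: str | None = None


def _group_values(cohort: CohortTable, column: str) -> dict[str, np.ndarray]:
    df = cohort.df
    return {
        g: df.loc[df["diagnosis"] == g, column].to_numpy(dtype=float)
        for g in cohort.groups()
    }


def _anova(groups: dict[str, np.ndarray]) -> tuple[float, float, bool]:
    arrays = list(groups.values())
    if all(np.ptp(a) == 0 for a in arrays if len(a)):
        return float("nan"), float("nan"), True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrays)
    if not np.isfinite(f):
        return float(f), float(p), True
    return float(f), float(p), False


def _homogeneity(counts: pd.DataFrame) -> tuple[float, float, bool]:
    """Pearson chi-square test that a binary variable is homogeneous across groups.

    ``counts``: groups x 2 table of (yes, no) counts.  A variable constant in
    the whole sample has statistic 0 and p = 1 by convention.
    """
    table = counts.to_numpy(dtype=float)
    if (table.sum(axis=0) == 0).any():
        return 0.0, 1.0, False
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p), False


def cochran_q(data: np.ndarray) -> tuple[float, float]:
    """Literal Cochran Q for a subjects x treatments binary layout.

    Provided for matched repeated-measures designs; the between-group
    baseline comparisons use the chi-square homogeneity test instead.
    """
    arr = np.asarray(data)
    if np.ptp(arr, axis=1).max(initial=0) == 0:
        # every subject identical across treatments: no discordance, Q = 0 by convention
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _sm_cochrans_q(arr, return_object=True)
    return float(res.statistic), float(res.pvalue)


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.1f} ({np.std(x, ddof=1):.1f})" if len(x) > 1 else f"{np.mean(x):.1f} (—)"


def baseline_table(cohort: CohortTable) -> list[GroupComparisonRow]:
    """Group comparison of age, LOS, CCI, sex, and the five history flags.

    Intended for the patient-baseline table; requires at least two diagnosis
    groups with two or more records each for the continuous tests.
    """
    groups = cohort.groups()
    if len(groups) < 2:
        raise ValidationError("baseline_table needs at least 2 diagnosis groups")
    rows: list[GroupComparisonRow] = []

    for var in ("age", "los_days", "cci"):
        gv = _group_values(cohort, var)
        stat, p, degenerate = _anova(gv)
        rows.append(
            GroupComparisonRow(
                variable=var,
                summaries={g: _fmt_mean_sd(v) for g, v in gv.items()},
                test="anova",
                statistic=stat,
                p_value=p,
                degenerate=degenerate,
            )
        )

    df = cohort.df
    for var, positive in [("sex", "female"), *[(c, 1) for c in FLAG_COLS]]:
        yes = {g: int((df.loc[df["diagnosis"] == g, var] == positive).sum()) for g in groups}
        n = {g: int((df["diagnosis"] == g).sum()) for g in groups}
        counts = pd.DataFrame({"yes": yes, "no": {g: n[g] - yes[g] for g in groups}})
        stat, p, degenerate = _homogeneity(counts)
        rows.append(
            GroupComparisonRow(
                variable="sex_female" if var == "sex" else var,
                summaries={g: f"{yes[g]} ({100 * yes[g] / n[g]:.1f})" for g in groups},
                test="categorical_homogeneity",
                statistic=stat,
                p_value=p,
                degenerate=degenerate,
            )
        )
    return rows


def rdoc_group_comparison(
    cohort: CohortTable,
    domains: Sequence[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    equal_var: bool = True,
    bonferroni: bool = False,
) -> tuple[list[GroupComparisonRow], list[PosthocResult]]:
    """Per-domain ANOVA across diagnosis groups, with pairwise post hoc t-tests.

    Post hoc rows are produced only for domains whose omnibus ANOVA has
    p < alpha (a non-significant domain gets no post hoc entry).  Pairs with
    a group of fewer than 2 records are skipped with a logged warning.
    """
    domains = list(domains) if domains is not None else cohort.score_columns
    groups = cohort.groups()
    rows: list[GroupComparisonRow] = []
    posthoc: list[PosthocResult] = []
    n_pairs = len(list(combinations(groups, 2)))

    for d in domains:
        gv = _group_values(cohort, d)
        stat, p, degenerate = _anova(gv)
        rows.append(
            GroupComparisonRow(
                variable=d,
                summaries={g: f"{np.mean(v):.3f} ({np.std(v, ddof=1):.3f})" for g, v in gv.items()},
                test="anova",
                statistic=stat,
                p_value=p,
                degenerate=degenerate,
            )
        )
        if degenerate or not (p < alpha):
            continue
        for a, b in combinations(groups, 2):
            if len(gv[a]) < 2 or len(gv[b]) < 2:
                logger.warning("post hoc %s: pair (%s, %s) skipped, group too small", d, a, b)
                continue
            t, tp = sps.ttest_ind(gv[a], gv[b], equal_var=equal_var)
            if bonferroni:
                tp = min(1.0, tp * n_pairs)
            hi, lo = (a, b) if np.mean(gv[a]) >= np.mean(gv[b]) else (b, a)
            posthoc.append(
                PosthocResult(
                    domain=d,
                    pair=(a, b),
                    direction=f"{hi} > {lo}",
                    t_statistic=float(t),
                    p_value=float(tp),
                )
            )
    return rows, posthoc


def _design(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in columns])
    return X


def _female(df: pd.DataFrame) -> pd.Series:
    return (df["sex"] == "female").astype(float)


def covariate_regression(
    cohort: CohortTable,
    domains: Sequence[str] | None = None,
    scale: float = SCORE_SCALE_DEFAULT,
) -> list[RegressionEffect]:
    """OLS of each domain score (x ``scale``) on age, sex (female=1), and CCI.

    One model per domain; a rank-deficient design flags that model's effects
    and the remaining domains are still fit.
    """
    domains = list(domains) if domains is not None else cohort.score_columns
    if len(cohort) < 10:
        raise ValidationError("covariate_regression needs >= 10 records")
    df = cohort.df.assign(sex_female=_female(cohort.df))
    terms = ["age", "sex_female", "cci"]
    X = _design(df, terms)
    effects: list[RegressionEffect] = []
    rank_ok = np.linalg.matrix_rank(X) == X.shape[1]
    for d in domains:
        model_id = f"ols_{d}"
        y = df[d].to_numpy(dtype=float) * scale
        if not rank_ok:
            logger.warning("%s: design matrix rank-deficient, model flagged", model_id)
            for t in ["const", *terms]:
                effects.append(
                    RegressionEffect(model_id, d, t, float("nan"), None, float("nan"),
                                     float("nan"), float("nan"), len(df), flag="collinear_design")
                )
            continue
        res = sm.OLS(y, X).fit()
        ci = res.conf_int(alpha=0.05)
        for i, t in enumerate(["const", *terms]):
            effects.append(
                RegressionEffect(
                    model_id=model_id,
                    outcome=d,
                    term=t,
                    estimate=float(res.params[i]),
                    or_or_hr=None,
                    ci_low=float(ci[i, 0]),
                    ci_high=float(ci[i, 1]),
                    p_value=float(res.pvalues[i]),
                    n_used=int(res.nobs),
                )
            )
    return effects


def los_logistic(
    cohort: CohortTable,
    group: str,
    domains: Sequence[str] | None = None,
    threshold: float = 3.0,
    scale: float = SCORE_SCALE_DEFAULT,
    adjust: Sequence[str] = ("age", "cci", "sex_female"),
) -> list[RegressionEffect]:
    """Logistic regression of the >threshold-day stay within one diagnosis group.

    Predictors: the five domain scores (x ``scale``) plus the ``adjust``
    covariates (by default age, CCI, and sex coded female=1).  Reports
    OR = exp(beta) with Wald 95% CIs.  Complete separation or
    non-convergence flags the whole model (NaN estimates, no silent output).
    """
    if group not in DIAGNOSES:
        raise ValidationError(f"unknown diagnosis group {group!r}")
    domains = list(domains) if domains is not None else cohort.score_columns
    df = cohort.df[cohort.df["diagnosis"] == group].copy()
    if len(df) < 20:
        logger.warning("los_logistic(%s): only %d admissions, estimates unstable", group, len(df))
    df = df.assign(sex_female=_female(df))
    for d in domains:
        df[f"{d}_pts"] = df[d].to_numpy(dtype=float) * scale
    terms = [f"{d}_pts" for d in domains] + list(adjust)
    term_labels = list(domains) + list(adjust)
    y = los_binary(df["los_days"].to_numpy(), threshold)
    X = _design(df, terms)
    model_id = f"logit_{group}"

    flag = None
    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(method="newton", maxiter=MAXITER, tol=TOL, disp=0)
        if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.bse)):
            flag = "nonconvergence"
    except Exception as exc:  # separation raises in newton
        flag = f"separation_or_singular: {type(exc).__name__}"

    effects: list[RegressionEffect] = []
    labels = ["const", *term_labels]
    if flag is not None:
        logger.warning("%s flagged: %s", model_id, flag)
        for t in labels:
            effects.append(
                RegressionEffect(model_id, f"los_gt{threshold:g}", t, float("nan"), float("nan"),
                                 float("nan"), float("nan"), float("nan"), len(df), flag=flag)
            )
        return effects

    ci = res.conf_int(alpha=0.05)
    for i, t in enumerate(labels):
        effects.append(
            RegressionEffect(
                model_id=model_id,
                outcome=f"los_gt{threshold:g}",
                term=t,
                estimate=float(res.params[i]),
                or_or_hr=float(np.exp(res.params[i])),
                ci_low=float(np.exp(ci[i, 0])),
                ci_high=float(np.exp(ci[i, 1])),
                p_value=float(res.pvalues[i]),
                n_used=int(res.nobs),
            )
        )
    return effects


def cox_secondary(
    cohort: CohortTable,
    domain: str,
    scale: float = SCORE_SCALE_DEFAULT,
) -> RegressionEffect:
    """Cox model of time to discharge for one domain, without the other four.

    Hazard of discharge ~ domain score (x ``scale``) + age + sex + CCI +
    diagnosis indicators (depression reference).  All discharges are observed
    events (no censoring); ties are handled by Efron's method (the fitter's
    default).  HR < 1 means slower discharge, i.e. a longer stay.
    """
    df = cohort.df
    model_id = f"cox_{domain}"
    data = pd.DataFrame(
        {
            "duration": df["los_days"].to_numpy(dtype=float),
            "event": np.ones(len(df), dtype=int),
            "score_pts": df[domain].to_numpy(dtype=float) * scale,
            "age": df["age"].to_numpy(dtype=float),
            "sex_female": _female(df).to_numpy(),
            "cci": df["cci"].to_numpy(dtype=float),
            "dx_schizophrenia": (df["diagnosis"] == "schizophrenia").astype(float).to_numpy(),
            "dx_bipolar": (df["diagnosis"] == "bipolar_disorder").astype(float).to_numpy(),
        }
    )
    covars = [c for c in data.columns if c not in ("duration", "event")]
    zero_var = [c for c in covars if data[c].nunique() <= 1]
    if "score_pts" in zero_var:
        logger.warning("%s flagged: domain score has zero variance", model_id)
        return RegressionEffect(model_id, "discharge_hazard", domain, float("nan"), float("nan"),
                                float("nan"), float("nan"), float("nan"), len(df), flag="zero_variance")
    data = data.drop(columns=[c for c in zero_var])

    cph = CoxPHFitter()
    cph.fit(data, duration_col="duration", event_col="event")
    s = cph.summary.loc["score_pts"]
    return RegressionEffect(
        model_id=model_id,
        outcome="discharge_hazard",
        term=domain,
        estimate=float(s["coef"]),
        or_or_hr=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        n_used=len(data),
    )
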