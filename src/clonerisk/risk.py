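"""Survival screening and combined risk stratification.

Every subclone's inferred abundance is screened by univariate Cox
regression against both OS and EFS with Bonferroni correction; subclones
passing adjusted p < 0.01 on *both* endpoints form the outcome-predictive
set, whose summed abundance T stratifies patients at the median.  Binary
T / MRD / cytogenetics features combine into eight strata (MRD unknown is
grouped with MRD-positive; normal cytogenetics and MRD-negative are the
multivariate reference levels).  Kaplan-Meier curves, log-rank tests,
multivariate Cox fits and nested-model likelihood-ratio comparisons go
through lifelines.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._stats import bonferroni_adjust, cox_univariate

log = logging.getLogger(__name__)

ENDPOINTS = {"os": ("os_time", "os_event"), "efs": ("efs_time", "efs_event")}


def screen_prognostic(
    abundances: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.01,
    n_tests: int | None = None,
    min_patients: int = 50,
    exclude_flt3: bool = True,
) -> pd.DataFrame:
    """Univariate Cox screen of each subclone against OS and EFS.

    ``abundances`` is patients x subclones (index matching
    ``cohort.patient_id``).  FLT3-ITD-positive patients are excluded before
    fitting when the cohort carries a ``flt3_itd`` column.  Bonferroni
    adjustment spans the screened subclones within each endpoint
    (denominator ``n_tests``, default the number screened); a subclone is
    ``selected`` iff adjusted p < alpha on both endpoints.  Constant
    abundance columns are skipped with a warning.
    """
    cohort = cohort.set_index("patient_id") if "patient_id" in cohort else cohort
    if exclude_flt3 and "flt3_itd" in cohort.columns:
        cohort = cohort[cohort["flt3_itd"] == 0]
    common = abundances.index.intersection(cohort.index)
    if len(common) < min_patients:
        raise ValueError(f"only {len(common)} patients (need >= {min_patients})")
    ab = abundances.loc[common]
    cl = cohort.loc[common]
    rows = []
    for sub in ab.columns:
        x = ab[sub].to_numpy(dtype=float)
        row = {"subclone": sub}
        if np.ptp(x) == 0:
            warnings.warn(f"subclone {sub}: constant abundance, skipped")
            for ep in ENDPOINTS:
                row[f"hr_{ep}"] = np.nan
                row[f"p_{ep}"] = np.nan
            rows.append(row)
            continue
        for ep, (tcol, ecol) in ENDPOINTS.items():
            if cl[ecol].sum() == 0:
                raise ValueError(f"no {ep} events in cohort")
            fit = cox_univariate(cl[tcol].to_numpy(), cl[ecol].to_numpy(), x)
            row[f"hr_{ep}"] = fit["hr"]
            row[f"p_{ep}"] = fit["p"]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("subclone")
    m = n_tests if n_tests is not None else int(out["p_os"].notna().sum())
    for ep in ENDPOINTS:
        out[f"p_{ep}_adj"] = bonferroni_adjust(out[f"p_{ep}"].to_numpy(), m)
    out["selected"] = (out["p_os_adj"] < alpha) & (out["p_efs_adj"] < alpha)
    return out


def total_abundance_T(abundances: pd.DataFrame, selected) -> pd.Series:
    """Per-patient total abundance of the outcome-predictive subclones."""
    selected = list(selected)
    missing = set(selected) - set(abundances.columns)
    if missing:
        raise ValueError(f"unknown subclones: {sorted(missing)}")
    if not selected:
        warnings.warn("empty selected set; T is 0 for all patients")
        return pd.Series(0.0, index=abundances.index, name="T")
    return abundances[selected].sum(axis=1).rename("T")


def median_split(values) -> np.ndarray:
    """Binary high/low labels at the median; ties at the median go low."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    med = np.median(v)
    if np.ptp(v) == 0:
        raise ValueError("all values identical; no median split possible")
    hi = (v > med).astype(int)
    log.info("median split at %.4g: %d low / %d high (ties to low)",
             med, int((hi == 0).sum()), int(hi.sum()))
    return hi


def combine_strata(T_bin, mrd, cyto) -> pd.DataFrame:
    """Eight risk strata from binary T / MRD / cytogenetics.

    MRD missing (NA) is coerced to 1 ("positive or unknown").  Stratum id is
    ``4*cyto + 2*mrd + T``.
    """
    T_bin = np.asarray(T_bin, dtype=int)
    mrd = np.asarray(mrd, dtype=float)
    mrd_bin = np.where(np.isnan(mrd), 1, mrd).astype(int)
    cyto_bin = np.asarray(cyto, dtype=int)
    for name, v in (("T_bin", T_bin), ("mrd", mrd_bin), ("cyto", cyto_bin)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    out = pd.DataFrame({
        "T_bin": T_bin, "mrd_bin": mrd_bin, "cyto_bin": cyto_bin,
        "stratum": 4 * cyto_bin + 2 * mrd_bin + T_bin,
    })
    log.info("stratum sizes: %s",
             out["stratum"].value_counts().sort_index().to_dict())
    return out


def km_logrank(time, event, groups) -> dict:
    """Kaplan-Meier curves per group plus a k-group log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    curves = {}
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"group {g} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        })
    if len(curves) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    res = multivariate_logrank_test(time, groups, event)
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "df": len(curves) - 1,
        "p": float(res.p_value),
    }


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
             covariates: list) -> CoxPHFitter:
    cph = CoxPHFitter()
    cols = [duration_col, event_col, *covariates]
    try:
        cph.fit(df[cols], duration_col=duration_col, event_col=event_col)
    except Exception as e:  # lifelines raises ConvergenceError and others
        raise ValueError(f"Cox fit failed ({covariates}): {e}") from e
    return cph


def nested_model_test(
    cohort: pd.DataFrame,
    reduced: list,
    full: list,
    duration_col: str = "os_time",
    event_col: str = "os_event",
) -> dict:
    """Likelihood-ratio improvement test between nested Cox models.

    ``reduced`` must be nested in ``full``; the statistic is twice the gain
    in log partial likelihood against chi-square with df equal to the number
    of added covariates.  Identical models give statistic 0 and p = 1.
    """
    if not set(reduced) <= set(full):
        raise ValueError("reduced covariates must be nested in full")
    if set(reduced) == set(full):
        return {"statistic": 0.0, "df": 0, "p": 1.0}
    df = cohort.dropna(subset=list(full)).copy()
    if reduced:
        ll0 = _fit_cox(df, duration_col, event_col, list(reduced)).log_likelihood_
    else:
        ll0 = float(_null_cox_loglik(df, duration_col, event_col))
    ll1 = _fit_cox(df, duration_col, event_col, list(full)).log_likelihood_
    stat = max(2.0 * (ll1 - ll0), 0.0)
    df_diff = len(set(full) - set(reduced))
    return {"statistic": float(stat), "df": df_diff,
            "p": float(stats.chi2.sf(stat, df_diff))}


def _null_cox_loglik(df, duration_col, event_col):
    from ._stats import cox_loglik

    return cox_loglik(df[duration_col].to_numpy(), df[event_col].to_numpy(),
                      np.zeros(len(df)))


def multivariate_cox(
    cohort: pd.DataFrame,
    covariates: list,
    duration_col: str = "os_time",
    event_col: str = "os_event",
) -> pd.DataFrame:
    """Joint Cox fit; returns HR with 95% CI and p per covariate.

    Binary MRD/cytogenetics covariates enter with 0 (MRD-negative, normal
    cytogenetics) as the implicit reference level.  Constant or collinear
    covariates are rejected up front.
    """
    df = cohort.dropna(subset=list(covariates)).copy()
    X = df[list(covariates)].to_numpy(dtype=float)
    for i, cov in enumerate(covariates):
        if np.ptp(X[:, i]) == 0:
            raise ValueError(f"covariate {cov} is constant")
    if len(covariates) > 1:
        cc = np.corrcoef(X.T)
        iu = np.triu_indices(len(covariates), 1)
        if (np.abs(cc[iu]) > 0.999).any():
            raise ValueError("collinear covariate pair (|r| > 0.999)")
    cph = _fit_cox(df, duration_col, event_col, list(covariates))
    summ = cph.summary
    out = pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "hr_ci_low": summ["exp(coef) lower 95%"],
        "hr_ci_high": summ["exp(coef) upper 95%"],
        "p": summ["p"],
    })
    out.index.name = "covariate"
    return out
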