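"""Linear mixed-effects aging-trajectory models and related statistics.

Trajectories of a network measure y over exact age (days since birth) are
modelled per the study design as

    y ~ 1 + age * factor + (1 | subject)

with a binary factor (sex, M vs F reference; or trajectory group, Y vs X
reference), a random per-subject intercept, and maximum-likelihood
estimation. Age is centred at the grand mean and scaled to months
internally for conditioning; coefficients are reported per month and per
day. Wald t uses residual degrees of freedom (observations minus
fixed-effect count). The time effect alone is the equal-weight contrast of
the age slope over both factor levels (age + interaction / 2).

Mass-univariate application over edges/nodes/regions controls the family
with Benjamini-Hochberg FDR; slope distributions are compared between
groups with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .cohort import MONTH_DAYS

log = logging.getLogger(__name__)

__all__ = [
    "LMEResult",
    "fit_lme",
    "time_contrast",
    "mass_univariate_lme",
    "bh_fdr",
    "ks_compare",
    "si_trajectory_analysis",
]

_DEFAULT_REFERENCE = {"sex": "F", "group": "X"}


@dataclass(frozen=True)
class LMEResult:
    """One fitted trajectory model.

    ``params`` rows are fixed-effect terms (intercept, age, factor,
    age:factor) with estimate/se/t/p; age terms carry both per-month
    (``estimate``) and per-day (``estimate_per_day``) scales.
    """

    outcome: str
    factor: str | None
    factor_level: str | None
    params: pd.DataFrame
    cov: pd.DataFrame
    n_subjects: int
    n_observations: int
    df_resid: int
    converged: bool
    age_mean_days: float

    def term(self, name: str) -> pd.Series:
        return self.params.loc[name]


def _design(data: pd.DataFrame, outcome: str, factor: str | None,
            subject_col: str, age_col: str,
            reference: str | None):
    d = data.dropna(subset=[outcome, age_col, subject_col]).copy()
    if factor is not None:
        d = d.dropna(subset=[factor])
    # sort so the fit is invariant to input row order
    d = d.sort_values([subject_col, age_col], kind="stable")
    age_mean = float(d[age_col].mean())
    age_c = (d[age_col].to_numpy(float) - age_mean) / MONTH_DAYS
    cols = {"intercept": np.ones(len(d)), "age": age_c}
    level = None
    if factor is not None:
        levels = sorted(d[factor].astype(str).unique())
        if len(levels) != 2:
            raise ValueError(
                f"factor {factor!r} must have exactly 2 levels, got {levels}")
        if reference is not None:
            ref = reference
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not among {levels}")
        else:
            ref = _DEFAULT_REFERENCE.get(factor)
            if ref not in levels:
                ref = levels[0]
        level = [l for l in levels if l != ref][0]
        f = (d[factor].astype(str) == level).astype(float).to_numpy()
        cols[f"{factor}[{level}]"] = f
        cols[f"age:{factor}[{level}]"] = age_c * f
    X = pd.DataFrame(cols, index=d.index)
    return d, X, d[outcome].to_numpy(float), age_mean, level


def _fe_covariance(X: np.ndarray, groups: np.ndarray, sigma2: float,
                   tau2: float) -> np.ndarray:
    """GLS covariance of the fixed effects at the fitted variance
    components: inv(sum_g X_g' V_g^-1 X_g), V_g = sigma2 I + tau2 J.

    Well defined at the tau2 = 0 boundary (where the optimiser's Hessian can
    be singular)."""
    k = X.shape[1]
    info = np.zeros((k, k))
    tau2 = max(tau2, 0.0)
    for g in np.unique(groups):
        idx = groups == g
        Xg = X[idx]
        ng = Xg.shape[0]
        Vg = sigma2 * np.eye(ng) + tau2 * np.ones((ng, ng))
        info += Xg.T @ np.linalg.solve(Vg, Xg)
    return np.linalg.inv(info)


def fit_lme(data: pd.DataFrame, outcome: str, factor: str | None = None,
            subject_col: str = "subject_id", age_col: str = "age_days",
            reference: str | None = None) -> LMEResult:
    """ML fit of outcome ~ 1 + age * factor + (1 | subject).

    Non-convergent or singular fits are returned flagged
    (``converged=False``), never silently.
    """
    d, X, y, age_mean, level = _design(data, outcome, factor, subject_col,
                                       age_col, reference)
    groups = d[subject_col].to_numpy()
    n_subj = len(np.unique(groups))
    if len(d) < 2 or n_subj < 2:
        raise ValueError("need >= 2 observations from >= 2 subjects")
    k = X.shape[1]
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = MixedLM(y, X.to_numpy(), groups=groups)
            try:
                res = model.fit(reml=False, method="lbfgs")
            except np.linalg.LinAlgError:
                # lbfgs can fail at the zero random-variance boundary
                res = MixedLM(y, X.to_numpy(), groups=groups).fit(
                    reml=False, method="powell")
            converged = bool(res.converged)
            fe = np.asarray(res.fe_params)
            cov = _fe_covariance(X.to_numpy(), groups, float(res.scale),
                                 float(np.asarray(res.cov_re)[0, 0]))
            se = np.sqrt(np.diagonal(cov))
        except (np.linalg.LinAlgError, ValueError) as e:
            log.warning("LME fit failed for %s: %s", outcome, e)
            fe = np.full(k, np.nan)
            cov = np.full((k, k), np.nan)
            se = np.full(k, np.nan)
            converged = False
    df_resid = len(d) - k
    with np.errstate(invalid="ignore", divide="ignore"):
        t = fe / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df_resid)
    per_day = np.full(k, np.nan)
    for i, name in enumerate(X.columns):
        if name.startswith("age"):
            per_day[i] = fe[i] / MONTH_DAYS
    params = pd.DataFrame(
        dict(estimate=fe, se=se, t=t, p=p, estimate_per_day=per_day),
        index=list(X.columns))
    return LMEResult(outcome=outcome, factor=factor, factor_level=level,
                     params=params,
                     cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
                     n_subjects=n_subj, n_observations=len(d),
                     df_resid=df_resid, converged=converged,
                     age_mean_days=age_mean)


def time_contrast(result: LMEResult) -> pd.Series:
    """Age effect averaged over both factor levels with equal weight:
    contrast = age + 0.5 * age:factor, variance via c' Sigma c."""
    inter = [n for n in result.params.index if n.startswith("age:")]
    if not inter:
        raise ValueError("time contrast needs a fitted age x factor interaction")
    terms = ["age", inter[0]]
    c = pd.Series(0.0, index=result.params.index)
    c["age"] = 1.0
    c[inter[0]] = 0.5
    est = float(c @ result.params["estimate"])
    var = float(c @ result.cov @ c)
    se = np.sqrt(var)
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df=result.df_resid)
    return pd.Series(dict(estimate=est, se=se, t=t, p=p,
                          estimate_per_day=est / MONTH_DAYS),
                     name="time_contrast")


def bh_fdr(p: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (reject mask, q-values)."""
    rej, q, _, _ = multipletests(np.asarray(p, float), alpha=alpha,
                                 method="fdr_bh")
    return rej, q


def mass_univariate_lme(table: pd.DataFrame, unit_col: str,
                        outcome_col: str = "value",
                        factor: str | None = None,
                        term: str = "age",
                        alpha: float = 0.05,
                        uncorrected_threshold: float = 0.01,
                        subject_col: str = "subject_id",
                        age_col: str = "age_days",
                        reference: str | None = None) -> pd.DataFrame:
    """fit_lme per unit (edge/node/region) with BH-FDR across the family.

    ``term`` selects the reported coefficient ("age", the factor term, the
    interaction, or "time_contrast"). Units whose fit fails to converge are
    excluded from the FDR family (their count is logged) and returned with
    NaN q. Emits both the q < alpha and the uncorrected p < 0.01 masks.
    """
    rows = []
    for unit, grp in table.groupby(unit_col, sort=True):
        try:
            res = fit_lme(grp, outcome_col, factor=factor,
                          subject_col=subject_col, age_col=age_col,
                          reference=reference)
            if term == "time_contrast":
                tr = time_contrast(res)
            else:
                tr = res.term(term)
            rows.append(dict(unit=unit, estimate=tr["estimate"], t=tr["t"],
                             p=tr["p"], sign=float(np.sign(tr["estimate"])),
                             converged=res.converged
                             and np.isfinite(tr["p"])))
        except (ValueError, KeyError) as e:
            log.warning("unit %s: %s", unit, e)
            rows.append(dict(unit=unit, estimate=np.nan, t=np.nan, p=np.nan,
                             sign=np.nan, converged=False))
    out = pd.DataFrame(rows).set_index("unit")
    ok = out["converged"] & out["p"].notna()
    n_failed = int((~ok).sum())
    if n_failed:
        log.warning("%d unit(s) excluded from the FDR family", n_failed)
    out["q"] = np.nan
    out["significant_fdr"] = False
    if ok.any():
        rej, q = bh_fdr(out.loc[ok, "p"].to_numpy(), alpha=alpha)
        out.loc[ok, "q"] = q
        out.loc[ok, "significant_fdr"] = rej
    out["significant_uncorrected"] = out["p"] < uncorrected_threshold
    return out


def ks_compare(slopes_a: Sequence[float],
               slopes_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic (sup ECDF difference) and
    asymptotic p."""
    a = np.asarray(slopes_a, float)
    b = np.asarray(slopes_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def si_trajectory_analysis(seg_table: pd.DataFrame,
                           outcome: str = "si3",
                           min_subjects: int = 3) -> pd.DataFrame:
    """Slope table for SI trajectories: overall, by sex, by cohort and by
    trajectory group, on non-excluded subjects with a defined SI.

    Factor models additionally report the factor term, interaction and the
    equal-weight time contrast. Strata with fewer than ``min_subjects``
    subjects are skipped with a warning.
    """
    d = seg_table.copy()
    if "excluded" in d.columns:
        d = d[~d["excluded"].astype(bool)]
    if "defined" in d.columns:
        d = d[d["defined"].astype(bool)]
    d = d.dropna(subset=[outcome])
    rows = []

    def _one(frame: pd.DataFrame, analysis: str, stratum: str,
             factor: str | None):
        if frame["subject_id"].nunique() < max(min_subjects, 2):
            warnings.warn(f"stratum {analysis}/{stratum}: fewer than "
                          f"{min_subjects} subjects; skipped")
            return
        try:
            res = fit_lme(frame, outcome, factor=factor)
        except ValueError as e:
            warnings.warn(f"stratum {analysis}/{stratum}: {e}")
            return
        terms = dict(res.params.iterrows())
        if factor is not None:
            terms["time_contrast"] = time_contrast(res)
        for name, tr in terms.items():
            rows.append(dict(
                analysis=analysis, stratum=stratum, term=name,
                estimate=tr["estimate"], se=tr["se"], t=tr["t"], p=tr["p"],
                estimate_per_day=tr.get("estimate_per_day", np.nan),
                n_subjects=res.n_subjects, n_observations=res.n_observations,
                converged=res.converged))

    _one(d, "overall", "all", None)
    if "sex" in d.columns and d["sex"].nunique() == 2:
        _one(d, "age_by_sex", "all", "sex")
        for sex, grp in d.groupby("sex"):
            _one(grp, "by_sex", str(sex), None)
    if "group" in d.columns and d["group"].nunique() == 2:
        _one(d, "age_by_group", "all", "group")
        for g, grp in d.groupby("group"):
            _one(grp, "by_group", str(g), None)
    if "cohort" in d.columns:
        for c, grp in d.groupby("cohort"):
            _one(grp, "by_cohort", str(c), None)
    return pd.DataFrame(rows)
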