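"""Covariate-adjusted group comparison of temporal statistics.

The design follows the classic two-stage pattern: nuisance covariates
(age, and in a robustness pass acquisition site and full-scale IQ) are
regressed out of each statistic on the pooled sample with the group label
excluded from the design, and the residuals are compared between groups
with a two-tailed pooled-variance t-test, Bonferroni-corrected over the K
states within each metric family.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["regress_out", "two_sample_t", "bonferroni", "run_group_analysis"]

METRIC_COLUMNS = ("fractional_occupancy", "mean_lifetime", "mean_interval")
DEFAULT_COVARIATE_SETS = (("age",), ("age", "site", "fiq"))


def _design_matrix(covariate_table: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Intercept + numeric covariates + one-hot site (reference level dropped)."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(covariate_table))}
    for name in covariates:
        if name not in covariate_table.columns:
            raise ValueError(f"covariate {name!r} missing from the covariate table")
        col = covariate_table[name]
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
        if name == "site" or not pd.api.types.is_numeric_dtype(col):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[name] = col.to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=covariate_table.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the columns that do not add rank, in order
        keep: list[str] = []
        collinear: list[str] = []
        for c in design.columns:
            trial = design[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(c)
            else:
                collinear.append(c)
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")
    return design


def regress_out(values: np.ndarray, covariate_table: pd.DataFrame,
                covariates: Sequence[str]) -> np.ndarray:
    """OLS residuals of ``values`` on an intercept plus the covariates.

    The group label is never part of the design, so group differences
    survive adjustment. With an empty covariate set the values are simply
    mean-centered (intercept-only fit).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) != len(covariate_table):
        raise ValueError("values must be 1-D and aligned with the covariate table")
    design = _design_matrix(covariate_table, covariates)
    fit = sm.OLS(values, design.to_numpy()).fit()
    return np.asarray(fit.resid)


def two_sample_t(values: np.ndarray, groups: Sequence[str], case_label: str,
                 control_label: str, equal_var: bool = True) -> tuple[float, float, int]:
    """Two-tailed two-sample t-test, case minus control.

    Pooled-variance by default (df = n1 + n2 - 2); Welch via ``equal_var=False``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    case = values[groups == case_label]
    control = values[groups == control_label]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.var(case, ddof=1) == 0.0 and np.var(control, ddof=1) == 0.0:
        if np.mean(case) == np.mean(control):
            return 0.0, 1.0, len(case) + len(control) - 2
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(case, control, equal_var=equal_var)
    df = res.df if hasattr(res, "df") else len(case) + len(control) - 2
    return float(res.statistic), float(res.pvalue), int(round(float(df)))


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Family-wise significance flags: p_i < alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < alpha / p.size


def run_group_analysis(metrics: pd.DataFrame, manifest: pd.DataFrame,
                       covariate_sets: Sequence[Sequence[str]] = DEFAULT_COVARIATE_SETS,
                       alpha: float = 0.05,
                       case_label: str = "case", control_label: str = "control",
                       equal_var: bool = True) -> pd.DataFrame:
    """Test every (metric, state) for a group difference under each covariate set.

    ``metrics`` is the tidy per-(subject, state) table from
    :func:`brainstates.temporal.cohort_metrics`. Rows with a missing value
    (state never visited, or visited once for intervals) are dropped per
    state with counts logged; a state missing in more than half the
    subjects is still tested but flagged ``low_coverage``. The Bonferroni
    family is the K states within one metric and covariate set; an
    uncorrected flag is reported alongside because correction families
    differ between toolboxes.
    """
    covars = manifest.set_index("subject_id")
    states = sorted(metrics["state"].unique())
    n_subjects = metrics["subject_id"].nunique()
    out_rows = []
    for cov_set in covariate_sets:
        cov_set = tuple(cov_set)
        for metric in METRIC_COLUMNS:
            if metric not in metrics.columns:
                continue
            per_state = []
            for k in states:
                sub = metrics[metrics["state"] == k][["subject_id", metric]].dropna()
                if len(sub) < len(metrics[metrics["state"] == k]):
                    logger.info(
                        "metric %s state %d: dropped %d subject(s) with undefined values",
                        metric, k, len(metrics[metrics["state"] == k]) - len(sub),
                    )
                tab = covars.loc[sub["subject_id"]]
                groups = tab["group"].to_numpy()
                n_case = int((groups == case_label).sum())
                n_control = int((groups == control_label).sum())
                try:
                    adjusted = regress_out(sub[metric].to_numpy(), tab, cov_set)
                    t, p, df = two_sample_t(adjusted, groups, case_label,
                                            control_label, equal_var=equal_var)
                except ValueError as exc:
                    logger.warning("metric %s state %d (%s): %s", metric, k,
                                   "+".join(cov_set) or "none", exc)
                    t, p, df = np.nan, np.nan, 0
                per_state.append({
                    "metric": metric, "state": k,
                    "covariate_set": "+".join(cov_set) if cov_set else "none",
                    "t": t, "p": p, "df": df,
                    "n_case": n_case, "n_control": n_control,
                    "low_coverage": len(sub) < 0.5 * n_subjects,
                })
            pvals = np.array([r["p"] for r in per_state])
            ok = np.isfinite(pvals)
            flags = np.zeros(len(per_state), dtype=bool)
            if ok.any():
                flags[ok] = pvals[ok] < alpha / len(per_state)
            for r, sig in zip(per_state, flags):
                r["significant"] = bool(sig)
                r["significant_uncorrected"] = bool(np.isfinite(r["p"]) and r["p"] < alpha)
            out_rows.extend(per_state)
    cols = ["metric", "state", "covariate_set", "t", "p", "df", "significant",
            "significant_uncorrected", "n_case", "n_control", "low_coverage"]
    return pd.DataFrame(out_rows)[cols]
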