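"""Group-level statistics: demographics, covariate-adjusted metric
comparisons, WM-GM metric coupling, and brain-behavior partial correlation.

The inference ladder mirrors a standard two-group neuroimaging analysis:

1. demographics — summary-statistic t-tests and Yates-corrected chi-square;
2. topological metrics — per node/metric linear model (group + sex + age +
   education + parental education) with an F-test on group, Bonferroni
   within the metric family, then post-hoc two-sample t-tests on survivors;
3. pairwise Pearson correlation between significant WM and GM nodal
   metrics within each group;
4. partial correlation between significant metrics and behavior scores,
   controlling age, education and parental education.

All adjusted p-values are Bonferroni (min(1, p * family)); raw and
adjusted p are always reported together with the family size used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SubjectRecord

__all__ = [
    "StatResult",
    "bonferroni",
    "ttest_from_summary",
    "chi2_contingency_yates",
    "subjects_frame",
    "group_compare_metrics",
    "wm_gm_interaction",
    "brain_behavior_partial_corr",
]

COVARIATE_COLS = ["sex", "age", "edu_years", "mother_edu_years", "father_edu_years"]
CONTROL_COLS = ["age", "edu_years", "mother_edu_years", "father_edu_years"]


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: float
    p_raw: float
    p_adj: float
    family: int
    direction: str = ""  # e.g. "TBI>NC"

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "family": self.family,
            "direction": self.direction,
        }


def bonferroni(p: float, family: int) -> float:
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if family < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * family)


def ttest_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    mode: str = "pooled",
    name: str = "ttest_summary",
) -> StatResult:
    """Two-sided independent-samples t-test from printed summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    diff = mean1 - mean2
    if sd1 == 0 and sd2 == 0:
        if diff == 0:
            return StatResult(name, 0.0, n1 + n2 - 2, 1.0, 1.0, 1)
        t, df = np.inf * np.sign(diff), n1 + n2 - 2
        return StatResult(name, float(t), df, 0.0, 0.0, 1)
    if mode == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif mode == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError("mode must be 'pooled' or 'welch'")
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    return StatResult(name, float(t), float(df), float(p), float(p), 1)


def chi2_contingency_yates(
    table, name: str = "chi2_yates", correction: bool = True
) -> StatResult:
    """Chi-square test on a 2x2 table, Yates-corrected by default."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return StatResult(name, float(chi2), float(dof), float(p), float(p), 1)


def subjects_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Subject table as a DataFrame indexed by subject_id."""
    df = pd.DataFrame([vars(r) for r in records]).set_index("subject_id")
    return df


def _design_matrix(subjects: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicator + covariates; collinear columns dropped."""
    cols = {"intercept": np.ones(len(subjects))}
    cols["group_TBI"] = (subjects["group"] == "TBI").to_numpy(float)
    cols["sex_M"] = (subjects["sex"] == "M").to_numpy(float)
    for c in ("age", "edu_years", "mother_edu_years", "father_edu_years"):
        cols[c] = subjects[c].to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(j)
        else:
            warnings.warn(f"covariate {names[j]} is collinear and was dropped")
    return X[:, keep], [names[j] for j in keep]


def group_compare_metrics(
    values: pd.DataFrame,
    subjects: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted group comparison per outcome column.

    ``values``: one row per subject (index must match ``subjects``), one
    column per (node, metric) outcome. Stage 1 fits each outcome on
    group + sex + age + education + parental education and F-tests the
    group term; stage 2 runs plain two-sample t-tests on Bonferroni
    survivors, Bonferroni-adjusted within the survivor family. Returns a
    tidy frame with one row per outcome (stage-2 columns NaN for
    non-survivors).
    """
    subjects = subjects.loc[values.index]
    counts = subjects["group"].value_counts()
    if counts.get("NC", 0) < 3 or counts.get("TBI", 0) < 3:
        raise ValueError("need at least 3 subjects per group")
    X, names = _design_matrix(subjects)
    j_group = names.index("group_TBI")
    family = family_size or values.shape[1]
    n, p_cols = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    rows = []
    tbi = (subjects["group"] == "TBI").to_numpy()
    for col in values.columns:
        y = values[col].to_numpy(float)
        if np.allclose(y, y[0]):
            rows.append(
                dict(outcome=col, f_stat=0.0, df1=1, df2=n - p_cols, p_raw=1.0,
                     p_adj=1.0, family=family, significant=False)
            )
            continue
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - p_cols)
        se = np.sqrt(max(sigma2 * XtX_inv[j_group, j_group], 0.0))
        tval = beta[j_group] / se if se > 0 else 0.0
        fstat = tval**2
        p_raw = float(stats.f.sf(fstat, 1, n - p_cols))
        p_adj = bonferroni(p_raw, family)
        rows.append(
            dict(outcome=col, f_stat=float(fstat), df1=1, df2=n - p_cols,
                 p_raw=p_raw, p_adj=p_adj, family=family,
                 significant=p_adj < alpha)
        )
    out = pd.DataFrame(rows).set_index("outcome")
    survivors = out.index[out["significant"]]
    out["t_posthoc"] = np.nan
    out["p_posthoc_raw"] = np.nan
    out["p_posthoc_adj"] = np.nan
    out["direction"] = ""
    fam2 = max(len(survivors), 1)
    for col in survivors:
        y = values[col].to_numpy(float)
        t, p = stats.ttest_ind(y[tbi], y[~tbi], equal_var=True)
        out.loc[col, "t_posthoc"] = float(t)
        out.loc[col, "p_posthoc_raw"] = float(p)
        out.loc[col, "p_posthoc_adj"] = bonferroni(float(p), fam2)
        out.loc[col, "direction"] = "TBI>NC" if t > 0 else "TBI<NC"
    return out


def wm_gm_interaction(
    wm_values: pd.DataFrame,
    gm_values: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation between every (WM outcome, GM outcome) pair
    across subjects of one group, Bonferroni-adjusted over pairs."""
    if len(wm_values) != len(gm_values) or len(wm_values) < 3:
        raise ValueError("need matched subjects, at least 3")
    pairs = [(w, g) for w in wm_values.columns for g in gm_values.columns]
    family = max(len(pairs), 1)
    rows = []
    for w, g in pairs:
        x = wm_values[w].to_numpy(float)
        y = gm_values[g].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"constant metric vector for pair ({w}, {g}); skipped")
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            dict(wm=w, gm=g, r=float(r), p_raw=float(p),
                 p_adj=bonferroni(float(p), family), family=family,
                 significant=bonferroni(float(p), family) < alpha)
        )
    return pd.DataFrame(rows)


def brain_behavior_partial_corr(
    metric: np.ndarray,
    behavior: np.ndarray,
    controls: np.ndarray | pd.DataFrame | None = None,
    name: str = "partial_corr",
) -> StatResult:
    """Partial Pearson correlation controlling nuisance covariates.

    Both variables are residualized on an intercept plus the control
    columns (collinear controls dropped with a warning); r is the Pearson
    correlation of the residuals and p comes from the t transform with
    df = n - n_controls - 2. With no controls this is the plain Pearson
    correlation.
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(behavior, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("metric and behavior must have equal length")
    if controls is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(controls, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    if n <= Z.shape[1] + 2:
        raise ValueError("need n > number of controls + 2")
    C = np.column_stack([np.ones(n), Z])
    keep = [0]
    for j in range(1, C.shape[1]):
        cand = C[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(j)
        else:
            warnings.warn(f"control column {j - 1} is collinear and was dropped")
    C = C[:, keep]
    proj = C @ np.linalg.lstsq(C, np.column_stack([x, y]), rcond=None)[0]
    rx, ry = (np.column_stack([x, y]) - proj).T
    k = C.shape[1] - 1
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("residual variance is zero; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return StatResult(name, r, float(df), p, p, 1,
                      direction="positive" if r > 0 else "negative")
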