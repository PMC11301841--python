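"""Cohort-level statistics for two-eye ophthalmic data.

All analyses accept a table with one row per eye and account for the
correlation between the two eyes of a subject:

* group comparisons use generalized estimating equations (GEE) with an
  exchangeable working correlation and Bonferroni-adjusted pairwise
  contrasts;
* logistic models for diffuse chorioretinal atrophy (DCA) and linear models
  for visual-field mean deviation (MD) use subject-clustered robust
  standard errors;
* diagnostic cut-offs come from ROC analysis with the Youden index
  J = sensitivity + specificity - 1, with DeLong standard errors for the
  AUC, overall and within age strata.

Continuous predictors in the logistic models are Z-standardized on the
analysis sample (pooling both eyes), so odds ratios are per 1 SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import EXCLUSION_REASONS

__all__ = [
    "apply_exclusions",
    "compare_groups",
    "fit_dca_logistic",
    "fit_md_linear",
    "roc_auc",
    "delong_se",
    "roc_cutoff",
    "age_stratified_table",
    "youden_index",
    "odds_decrease_percent",
    "GroupComparison",
    "RegressionResult",
    "ROCResult",
    "AGE_STRATA",
]

#: (label, lower, upper, lower_closed) — "All" plus four age bands; the first
#: band includes both endpoints, later bands are left-open.
AGE_STRATA: list[tuple[str, float, float, bool]] = [
    ("All", -np.inf, np.inf, True),
    ("18<=Age<=30", 18.0, 30.0, True),
    ("30<Age<=40", 30.0, 40.0, False),
    ("40<Age<=50", 40.0, 50.0, False),
    ("50<Age<=60", 50.0, 60.0, False),
]


def youden_index(sensitivity_pct: float, specificity_pct: float) -> float:
    """Youden's J from sensitivity and specificity given in percent."""
    return sensitivity_pct / 100.0 + specificity_pct / 100.0 - 1.0


def odds_decrease_percent(odds_ratio: float) -> float:
    """Percent decrease in odds implied by an odds ratio below 1."""
    return (1.0 - odds_ratio) * 100.0


# --------------------------------------------------------------------------
# Exclusions
# --------------------------------------------------------------------------

def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove eyes with any exclusion flag set.

    Flags are boolean columns named ``excl_<reason>``. An eye with several
    reasons is removed once; the ledger counts per-reason occurrences (which
    may therefore sum to more than the number of removed eyes) and removals
    per eye side.
    """
    flag_cols = [c for c in records.columns if c.startswith("excl_")]
    if flag_cols:
        flagged = records[flag_cols].fillna(False).astype(bool).any(axis=1)
    else:
        flagged = pd.Series(False, index=records.index)
    removed = records.loc[flagged]
    kept = records.loc[~flagged]
    by_reason = {c.removeprefix("excl_"): int(removed[c].sum()) for c in flag_cols}
    ledger = {
        "n_input": int(len(records)),
        "n_removed": int(flagged.sum()),
        "n_kept": int(len(kept)),
        "by_reason": by_reason,
        "by_side": removed["eye"].value_counts().to_dict() if "eye" in records else {},
        "by_reason_side": {
            c.removeprefix("excl_"): removed.loc[removed[c], "eye"].value_counts().to_dict()
            for c in flag_cols
        }
        if "eye" in records
        else {},
    }
    return kept, ledger


# --------------------------------------------------------------------------
# Group comparisons (GEE)
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Eye-clustered group contrast results for one outcome."""

    outcome: str
    group_means: pd.Series
    contrasts: pd.DataFrame  # pair, estimate, se, p_raw, p_adj
    n: int


def compare_groups(
    cohort: pd.DataFrame,
    outcome: str,
    adjusters: tuple[str, ...] = ("age", "AL"),
    group_col: str = "category",
    cluster_col: str = "subject_id",
) -> GroupComparison:
    """Compare an outcome across maculopathy groups with a marginal model.

    Fits a GEE of ``outcome ~ group + adjusters`` with exchangeable working
    correlation within subjects and robust standard errors, then reports all
    pairwise group contrasts with Bonferroni-adjusted p-values (raw p times
    the number of pairs, capped at 1).
    """
    cols = [outcome, group_col, cluster_col, *adjusters]
    data = cohort[cols].dropna()
    levels = sorted(data[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    counts = data.groupby(group_col)[cluster_col].nunique()
    if (counts < 2).any():
        raise ValueError("each group needs at least two subjects")

    X = pd.get_dummies(data[group_col], prefix="g", dtype=float).drop(
        columns=f"g_{levels[0]}"
    )
    for a in adjusters:
        X[a] = data[a].astype(float)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"singular design matrix; terms: {list(X.columns)}")
    model = sm.GEE(
        data[outcome].astype(float),
        X,
        groups=data[cluster_col],
        cov_struct=sm.cov_struct.Exchangeable(),
        family=sm.families.Gaussian(),
    )
    res = model.fit()

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    m = len(pairs)
    rows = []
    names = list(X.columns)
    for a, b in pairs:
        L = np.zeros(len(names))
        if f"g_{b}" in names:
            L[names.index(f"g_{b}")] = 1.0
        if f"g_{a}" in names:
            L[names.index(f"g_{a}")] = -1.0
        t = res.t_test(L)
        p_raw = float(np.squeeze(t.pvalue))
        rows.append(
            {
                "pair": f"{b}-{a}",
                "estimate": float(np.squeeze(t.effect)),
                "se": float(np.squeeze(t.sd)),
                "p_raw": p_raw,
                "p_adj": min(1.0, m * p_raw),
            }
        )
    return GroupComparison(
        outcome=outcome,
        group_means=data.groupby(group_col)[outcome].mean(),
        contrasts=pd.DataFrame(rows),
        n=len(data),
    )


# --------------------------------------------------------------------------
# Regression models
# --------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Coefficient table of one fitted model (one row per term)."""

    kind: str  # "logistic" | "linear"
    predictor: str
    table: pd.DataFrame
    n: int
    meta: dict = field(default_factory=dict)


def _zscore(x: pd.Series) -> tuple[pd.Series, float, float]:
    mu, sd = float(x.mean()), float(x.std(ddof=0))
    if sd == 0:
        raise ValueError(f"constant column {x.name!r} cannot be standardized")
    return (x - mu) / sd, mu, sd


def fit_dca_logistic(
    cohort: pd.DataFrame,
    predictor: str,
    outcome: str = "dca",
    covariates: tuple[str, ...] = ("age", "AL"),
    gender_col: str = "gender",
    cluster_col: str = "subject_id",
) -> RegressionResult:
    """Logistic model of DCA on a standardized choroidal predictor.

    The predictor and continuous covariates are Z-standardized on the
    analysis sample (both eyes pooled), gender enters as male = 1; standard
    errors are clustered by subject. The reported OR is the change in odds
    per 1 SD of the predictor.

    Raises
    ------
    ValueError
        On a one-class outcome, a constant predictor, or (quasi-)perfect
        separation.
    """
    cols = [outcome, predictor, cluster_col, gender_col, *covariates]
    data = cohort[cols].dropna()
    y = data[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")

    X = pd.DataFrame(index=data.index)
    stand: dict[str, tuple[float, float]] = {}
    for c in (predictor, *covariates):
        X[c], mu, sd = _zscore(data[c].astype(float))
        stand[c] = (mu, sd)
    X["gender_male"] = (data[gender_col] == "M").astype(float)
    X = sm.add_constant(X)

    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": data[cluster_col]})
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
    if np.any(np.abs(res.params) > 30):
        raise ValueError(
            "perfect or quasi-perfect separation detected (diverging coefficients)"
        )

    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "term": res.params.index,
            "B": res.params.to_numpy(),
            "SE": res.bse.to_numpy(),
            "OR": np.exp(res.params.to_numpy()),
            "OR_CI_low": np.exp(ci[0].to_numpy()),
            "OR_CI_high": np.exp(ci[1].to_numpy()),
            "p": res.pvalues.to_numpy(),
        }
    )
    return RegressionResult(
        kind="logistic",
        predictor=predictor,
        table=table,
        n=len(data),
        meta={"standardization": stand},
    )


def fit_md_linear(
    cohort: pd.DataFrame,
    predictor: str = "LA_V",
    outcome: str = "MD",
    covariates: tuple[str, ...] = ("age", "height", "AL", "corneal_curvature"),
    subset: str = "all",
    cluster_col: str = "subject_id",
    category_col: str = "category",
    vf_col: str = "vf_reliable",
) -> RegressionResult:
    """Linear model of visual-field MD on covariates plus one choroidal term.

    ``subset`` selects ``"all"`` eyes, ``"non_pm"`` (C0 + C1) or ``"pm"``
    (C2); only rows with a reliable visual field enter. Reports the
    unstandardized B with subject-clustered SE and 95% CI, plus the
    standardized beta.
    """
    data = cohort
    if vf_col in data.columns:
        data = data[data[vf_col].astype(bool)]
    if subset == "non_pm":
        data = data[data[category_col].isin(["C0", "C1"])]
    elif subset == "pm":
        data = data[data[category_col] == "C2"]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    cols = [outcome, predictor, cluster_col, *covariates]
    data = data[cols].dropna()
    terms = [*covariates, predictor]
    if len(data) < len(terms) + 3:
        raise ValueError(f"too few rows ({len(data)}) for {len(terms)} terms")

    X = sm.add_constant(data[terms].astype(float))
    y = data[outcome].astype(float)
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": data[cluster_col]})

    sy = float(y.std(ddof=0))
    betas = [
        np.nan
        if t == "const"
        else float(res.params[t]) * float(data[t].std(ddof=0)) / sy
        for t in res.params.index
    ]
    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "term": res.params.index,
            "B": res.params.to_numpy(),
            "SE": res.bse.to_numpy(),
            "beta": betas,
            "CI_low": ci[0].to_numpy(),
            "CI_high": ci[1].to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )
    return RegressionResult(
        kind="linear", predictor=predictor, table=table, n=len(data), meta={"subset": subset}
    )


# --------------------------------------------------------------------------
# ROC / Youden cut-offs
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Diagnostic cut-off for one predictor in one stratum."""

    predictor: str
    stratum: str
    orientation: str  # "lower" => smaller values indicate disease
    auc: float
    se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    youden: float
    n_pos: int
    n_neg: int


def roc_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the probability that a diseased value exceeds a healthy one
    (ties count half), computed from the rank-sum (Mann-Whitney) statistic."""
    from scipy.stats import rankdata

    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(values)
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def delong_se(values: np.ndarray, labels: np.ndarray) -> float:
    """DeLong standard error of the AUC (structural components)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    pos, neg = values[labels], values[~labels]
    m, n = pos.size, neg.size
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_cutoff(
    values: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    predictor: str = "",
    stratum: str = "All",
    orientation: str = "auto",
) -> ROCResult:
    """Optimal Youden cut-off and DeLong AUC for one predictor.

    Orientation is chosen so the AUC is >= 0.5 (for choroidal metrics, lower
    values indicate disease). Candidate cut-offs are the midpoints between
    consecutive sorted unique values; ties on J are broken by higher
    sensitivity, then by the smaller threshold.
    """
    v = np.asarray(pd.Series(values), float)
    y = np.asarray(pd.Series(labels)).astype(bool)
    keep = np.isfinite(v)
    v, y = v[keep], y[keep]
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError(f"stratum {stratum!r} has a single outcome class")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("predictor is constant")

    auc_hi = roc_auc(v, y)  # higher => disease
    if orientation == "auto":
        orientation = "higher" if auc_hi >= 0.5 else "lower"
    score = v if orientation == "higher" else -v
    auc = roc_auc(score, y)
    se = delong_se(score, y)

    cand = (uniq[:-1] + uniq[1:]) / 2.0
    if orientation == "higher":
        pred_pos = v[None, :] > cand[:, None]
    else:
        pred_pos = v[None, :] < cand[:, None]
    sens = (pred_pos & y[None, :]).sum(axis=1) / y.sum()
    spec = (~pred_pos & ~y[None, :]).sum(axis=1) / (~y).sum()
    j = sens + spec - 1.0
    # lexicographic: max J, then max sensitivity, then smallest threshold
    order = np.lexsort((cand, -sens, -j))
    best = order[0]

    return ROCResult(
        predictor=predictor,
        stratum=stratum,
        orientation=orientation,
        auc=float(auc),
        se=se,
        ci_low=float(max(0.0, auc - 1.959963984540054 * se)),
        ci_high=float(min(1.0, auc + 1.959963984540054 * se)),
        cutoff=float(cand[best]),
        sensitivity_pct=float(100 * sens[best]),
        specificity_pct=float(100 * spec[best]),
        youden=float(j[best]),
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def age_stratified_table(
    cohort: pd.DataFrame,
    predictors: tuple[str, ...] = ("ChT_V", "LA_V", "SA_V", "ChT_N2", "LA_N2", "SA_N2"),
    label_col: str = "dca",
    age_col: str = "age",
    strata: list[tuple[str, float, float, bool]] | None = None,
) -> pd.DataFrame:
    """ROC cut-off table for several predictors across age strata.

    Strata that are empty or contain a single outcome class yield a row of
    NaNs (reported missing, not an error). Returns a tidy DataFrame with one
    row per predictor x stratum.
    """
    strata = AGE_STRATA if strata is None else strata
    age = cohort[age_col].astype(float)
    rows = []
    for label, lo, hi, lo_closed in strata:
        mask = (age >= lo if lo_closed else age > lo) & (age <= hi)
        sub = cohort[mask]
        for p in predictors:
            try:
                r = roc_cutoff(sub[p], sub[label_col], predictor=p, stratum=label)
                rows.append(vars(r))
            except (ValueError, KeyError):
                rows.append(
                    {
                        "predictor": p,
                        "stratum": label,
                        "orientation": None,
                        "auc": np.nan,
                        "se": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "cutoff": np.nan,
                        "sensitivity_pct": np.nan,
                        "specificity_pct": np.nan,
                        "youden": np.nan,
                        "n_pos": int(sub[label_col].sum()) if label_col in sub else 0,
                        "n_neg": int((~sub[label_col].astype(bool)).sum())
                        if label_col in sub
                        else 0,
                    }
                )
    return pd.DataFrame(rows)
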