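"""Cohort statistics: group comparisons, logistic models, ROC evaluation.

Group comparisons pick the test from the variable type and a per-group
Shapiro-Wilk normality gate (t test vs Mann-Whitney U for continuous
variables; chi-square vs Fisher exact for categorical ones).  Logistic
regressions (maximum likelihood via statsmodels) report odds ratios with Wald
95% CIs, both unadjusted and under five sequential adjustment sets built from
age, sex, diastolic blood pressure, NYHA class IV and log NT-proBNP.  ROC
analysis computes the trapezoidal AUC (equal to the tie-corrected
Mann-Whitney statistic), a DeLong 95% CI and p-value against 0.5, and the
Youden-optimal operating point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "GroupComparison",
    "LogisticResult",
    "ROCResult",
    "StatReport",
    "compare_groups",
    "univariate_logistic",
    "adjusted_logistic",
    "combined_model",
    "roc_analysis",
    "analyze_cohort",
    "ADJUSTMENT_MODELS",
    "COMBINED_TERMS",
]

#: Sequential covariate-adjustment sets for the focal-variable models.
ADJUSTMENT_MODELS: dict[int, list[str]] = {
    1: ["age", "male"],
    2: ["age", "male", "dbp"],
    3: ["age", "male", "nyha_iv"],
    4: ["age", "male", "log_ntprobnp"],
    5: ["age", "male", "dbp", "nyha_iv", "log_ntprobnp"],
}

#: Terms of the combined multivariate discrimination model.
COMBINED_TERMS = [
    "dbp",
    "log_ntprobnp",
    "nyha_iv",
    "mean_TE_ratio",
    "RA_area_1_5",
    "RA_area_6_20",
]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t" | "mann-whitney" | "chi-square" | "fisher"
    p_value: float
    summaries: dict[str, str]  # group label -> formatted summary
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "test": self.test,
            "p_value": self.p_value,
            "summaries": self.summaries,
            "flags": self.flags,
        }


def _is_categorical(s: pd.Series) -> bool:
    return (
        s.dtype == object
        or isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == bool
    )


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group: str = "pc_label",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-group comparison with automatic test selection.

    Continuous variables: Shapiro-Wilk in each group at ``alpha``; both
    normal -> Student t test (mean/SD summaries), otherwise Mann-Whitney U
    (median/IQR summaries).  Categorical variables: chi-square, switching to
    Fisher exact when any expected cell count is < 5 (2x2 tables only;
    larger sparse tables keep chi-square and carry a flag).
    """
    data = cohort[[variable, group]].dropna()
    levels = sorted(data[group].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups in {group!r}, got {levels}")
    g0 = data.loc[data[group] == levels[0], variable]
    g1 = data.loc[data[group] == levels[1], variable]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError(
            f"{variable!r}: need >= 2 observations per group "
            f"(got {len(g0)} and {len(g1)})"
        )
    flags: list[str] = []

    if _is_categorical(data[variable]):
        table = pd.crosstab(data[group], data[variable])
        expected = scipy.stats.contingency.expected_freq(table.to_numpy())
        if (expected < 5).any() and table.shape == (2, 2):
            test = "fisher"
            _, p = scipy.stats.fisher_exact(table.to_numpy())
        else:
            test = "chi-square"
            if (expected < 5).any():
                flags.append("low expected counts; table larger than 2x2")
            chi = scipy.stats.chi2_contingency(table.to_numpy())
            p = chi.pvalue
        summaries = {}
        for lev, grp in ((levels[0], g0), (levels[1], g1)):
            counts = grp.value_counts()
            summaries[str(lev)] = "; ".join(
                f"{cat}: {int(cnt)} ({100 * cnt / len(grp):.0f}%)"
                for cat, cnt in counts.items()
            )
        return GroupComparison(variable, test, float(p), summaries, flags)

    x0 = g0.to_numpy(dtype=float)
    x1 = g1.to_numpy(dtype=float)
    normal = all(
        len(np.unique(x)) > 2 and scipy.stats.shapiro(x).pvalue > alpha
        for x in (x0, x1)
    )
    if normal:
        test = "t"
        p = float(scipy.stats.ttest_ind(x0, x1, equal_var=True).pvalue)
        summaries = {
            str(lev): f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f})"
            for lev, x in ((levels[0], x0), (levels[1], x1))
        }
    else:
        test = "mann-whitney"
        p = float(scipy.stats.mannwhitneyu(x0, x1, alternative="two-sided").pvalue)
        summaries = {}
        for lev, x in ((levels[0], x0), (levels[1], x1)):
            q25, q50, q75 = np.percentile(x, [25, 50, 75])
            summaries[str(lev)] = f"{q50:.2f} ({q25:.2f}-{q75:.2f})"
    return GroupComparison(variable, test, p, summaries, flags)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    se: float
    model_terms: list[str]
    n: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "odds_ratio": self.odds_ratio,
            "ci_95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "coef": self.coef,
            "se": self.se,
            "model_terms": self.model_terms,
            "n": self.n,
            "flags": self.flags,
        }


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


def _design(cohort: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design columns; encodes sex and NYHA indicators on demand."""
    cols = {}
    for t in terms:
        if t in cohort.columns and not _is_categorical(cohort[t]):
            cols[t] = cohort[t].astype(float)
        elif t == "male" and "sex" in cohort.columns:
            cols[t] = (cohort["sex"] == "male").astype(float)
        elif t == "nyha_iv" and "nyha" in cohort.columns:
            cols[t] = (cohort["nyha"] == "IV").astype(float)
        elif t == "sex":
            cols["male"] = (cohort["sex"] == "male").astype(float)
        elif t in cohort.columns:  # generic categorical -> indicator per level
            dummies = pd.get_dummies(cohort[t], prefix=t, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        else:
            raise KeyError(f"term {t!r} not found in cohort table")
    return pd.DataFrame(cols, index=cohort.index)


def _fit_logistic(
    cohort: pd.DataFrame, terms: list[str], outcome: str
) -> tuple[list[LogisticResult], np.ndarray, pd.Index]:
    X = _design(cohort, terms)
    data = pd.concat([X, cohort[outcome].rename("_y")], axis=1).dropna()
    y = data.pop("_y").astype(float)
    X = data
    n = len(X)
    flags: list[str] = []
    if n < len(X.columns) + 2:
        raise ValueError(f"too few complete observations (n={n}) for fit")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        flags.append("rank_deficient")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            flags.append("non_converged")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        flags.append(f"separation:{type(exc).__name__}")
        nan = math.nan
        results = [
            LogisticResult(t, nan, nan, nan, nan, nan, nan, list(X.columns), n,
                           flags=list(flags))
            for t in X.columns
        ]
        # Wald inference is meaningless under separation, but a lightly
        # ridge-penalised fit still yields usable predicted probabilities
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ridge = sm.Logit(y, Xc).fit_regularized(
                    alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500
                )
            probs = np.asarray(ridge.predict(Xc), dtype=float)
        except Exception:
            probs = np.full(n, math.nan)
        return results, probs, X.index

    params, bse, pvals = res.params, res.bse, res.pvalues
    results = []
    for t in X.columns:
        coef, se, p = float(params[t]), float(bse[t]), float(pvals[t])
        term_flags = list(flags)
        if abs(coef) > 15 or se > 50:
            term_flags.append("possible_separation")
        results.append(
            LogisticResult(
                term=t,
                odds_ratio=_safe_exp(coef),
                ci_low=_safe_exp(coef - 1.959963984540054 * se),
                ci_high=_safe_exp(coef + 1.959963984540054 * se),
                p_value=p,
                coef=coef,
                se=se,
                model_terms=list(X.columns),
                n=n,
                flags=term_flags,
            )
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probs = np.asarray(res.predict(Xc), dtype=float)
    return results, probs, X.index


def univariate_logistic(
    cohort: pd.DataFrame, variable: str, outcome: str = "pc_label"
) -> LogisticResult:
    """Single-predictor logistic fit of the congestion label on ``variable``."""
    results, _, _ = _fit_logistic(cohort, [variable], outcome)
    return results[0]


def adjusted_logistic(
    cohort: pd.DataFrame,
    variable: str,
    model_id: int,
    outcome: str = "pc_label",
) -> LogisticResult:
    """Focal-variable odds ratio under sequential adjustment set ``model_id``.

    Model 1 adjusts for age and sex; models 2-4 add diastolic blood
    pressure, NYHA IV, or log NT-proBNP respectively; model 5 adds all three.
    """
    if model_id not in ADJUSTMENT_MODELS:
        raise ValueError(
            f"model_id must be one of {sorted(ADJUSTMENT_MODELS)}, got {model_id}"
        )
    covs = [c for c in ADJUSTMENT_MODELS[model_id] if c != variable]
    results, _, _ = _fit_logistic(cohort, [variable] + covs, outcome)
    return results[0]


def combined_model(
    cohort: pd.DataFrame,
    terms: list[str] | None = None,
    outcome: str = "pc_label",
) -> tuple[list[LogisticResult], pd.Series]:
    """Multivariate fit over the combined clinical + respiratory terms.

    Returns per-term results and the in-sample predicted probabilities
    (indexed like the rows actually used), ready for ROC analysis.
    """
    terms = COMBINED_TERMS if terms is None else terms
    results, probs, index = _fit_logistic(cohort, terms, outcome)
    return results, pd.Series(probs, index=index, name="p_hat")


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float  # vs AUC = 0.5, DeLong
    sensitivity_pct: float
    specificity_pct: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_95": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "threshold": self.threshold,
        }


def _midrank(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC (tie-corrected Mann-Whitney) and its DeLong variance."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    r_all = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (r_all[:m] - r_pos) / n  # structural components, cases
    v10 = 1.0 - (r_all[m:] - r_neg) / m  # controls
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_analysis(scores, labels) -> ROCResult:
    """AUC with DeLong CI/p and the Youden-optimal operating point.

    The AUC is the trapezoidal area over all thresholds, identical to the
    Mann-Whitney pair statistic with ties counted half.  Ties in Youden's J
    break toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")

    auc, var = _delong_auc_variance(scores, labels)
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        ci_low, ci_high = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    else:
        p = 1.0 if auc == 0.5 else 0.0
        ci_low = ci_high = auc
    ci_low, ci_high = max(0.0, ci_low), min(1.0, ci_high)

    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.argmax(tpr[candidates])]
    return ROCResult(
        auc=auc,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        sensitivity_pct=float(tpr[best] * 100.0),
        specificity_pct=float((1.0 - fpr[best]) * 100.0),
        threshold=float(thresholds[best]),
    )


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------


@dataclass
class StatReport:
    """Machine-readable summary of the full statistical stage."""

    group_comparisons: list[GroupComparison]
    univariate: list[LogisticResult]
    adjusted: dict[str, dict[int, LogisticResult]]
    combined_terms: list[LogisticResult]
    combined_roc: ROCResult | None
    roc_single: dict[str, ROCResult]
    n_subjects: int
    n_complete: int

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_complete": self.n_complete,
            "group_comparisons": [c.to_dict() for c in self.group_comparisons],
            "univariate": [r.to_dict() for r in self.univariate],
            "adjusted": {
                v: {str(k): r.to_dict() for k, r in models.items()}
                for v, models in self.adjusted.items()
            },
            "combined_model": {
                "terms": [r.to_dict() for r in self.combined_terms],
                "roc": self.combined_roc.to_dict() if self.combined_roc else None,
            },
            "roc_single": {k: r.to_dict() for k, r in self.roc_single.items()},
        }

    def to_text(self) -> str:
        lines = [
            f"Cohort: {self.n_subjects} subjects ({self.n_complete} with complete features)",
            "",
            "== Group comparisons ==",
        ]
        for c in self.group_comparisons:
            summ = " vs ".join(f"{k}: {v}" for k, v in c.summaries.items())
            lines.append(f"{c.variable:>16s}  [{c.test}] p={c.p_value:.3g}  {summ}")
        lines += ["", "== Univariate logistic (outcome: pulmonary congestion) =="]
        for r in self.univariate:
            lines.append(
                f"{r.term:>16s}  OR {r.odds_ratio:.3f} "
                f"({r.ci_low:.3f}-{r.ci_high:.3f})  p={r.p_value:.3g}"
                + (f"  flags={r.flags}" if r.flags else "")
            )
        lines += ["", "== Adjusted models =="]
        for var, models in self.adjusted.items():
            for mid, r in models.items():
                lines.append(
                    f"{var:>16s}  model {mid}: OR {r.odds_ratio:.3f} "
                    f"({r.ci_low:.3f}-{r.ci_high:.3f})  p={r.p_value:.3g}"
                )
        lines += ["", "== ROC =="]
        for name, r in self.roc_single.items():
            lines.append(
                f"{name:>16s}  AUC {r.auc:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f}) "
                f"p={r.p_value:.3g}  sens {r.sensitivity_pct:.1f}% "
                f"spec {r.specificity_pct:.1f}%"
            )
        if self.combined_roc is not None:
            r = self.combined_roc
            lines.append(
                f"{'combined model':>16s}  AUC {r.auc:.3f} "
                f"({r.ci_low:.3f}-{r.ci_high:.3f}) p={r.p_value:.3g}  "
                f"sens {r.sensitivity_pct:.1f}% spec {r.specificity_pct:.1f}%"
            )
        return "\n".join(lines)


#: Respiratory variables carried through the adjusted models and single-ROC block.
FOCAL_VARIABLES = ["mean_TE_ratio", "RA_area_1_5", "RA_area_6_20"]

_CLINICAL_COMPARE = ["age", "sex", "dbp", "sbp", "nyha", "log_ntprobnp"]
_CLINICAL_UNIVARIATE = ["age", "male", "dbp", "nyha_iv", "log_ntprobnp"]


def analyze_cohort(
    cohort: pd.DataFrame,
    feature_cols: list[str] | None = None,
    outcome: str = "pc_label",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> StatReport:
    """Run the full statistical stage on a joined features + covariates table.

    Rows with missing values are dropped per analysis.  ``bh_correction``
    optionally applies Benjamini-Hochberg across the group-comparison
    p-values (off by default, matching unadjusted reporting).
    """
    from .features import FEATURE_COLUMNS

    feature_cols = FEATURE_COLUMNS if feature_cols is None else feature_cols
    present = [c for c in feature_cols if c in cohort.columns]
    n_subjects = len(cohort)
    n_complete = int(cohort[present].notna().all(axis=1).sum()) if present else 0

    comparisons = []
    for var in _CLINICAL_COMPARE + present:
        if var not in cohort.columns:
            continue
        try:
            comparisons.append(compare_groups(cohort, var, group=outcome, alpha=alpha))
        except ValueError:
            continue
    if bh_correction and comparisons:
        adj = multipletests([c.p_value for c in comparisons], method="fdr_bh")[1]
        for c, p in zip(comparisons, adj):
            c.flags.append(f"bh_adjusted_p={p:.4g}")

    univariate = []
    for var in _CLINICAL_UNIVARIATE + present:
        try:
            univariate.append(univariate_logistic(cohort, var, outcome=outcome))
        except (ValueError, KeyError):
            continue

    adjusted: dict[str, dict[int, LogisticResult]] = {}
    for var in FOCAL_VARIABLES:
        if var not in cohort.columns:
            continue
        adjusted[var] = {}
        for mid in ADJUSTMENT_MODELS:
            try:
                adjusted[var][mid] = adjusted_logistic(cohort, var, mid, outcome=outcome)
            except ValueError:
                continue

    roc_single: dict[str, ROCResult] = {}
    for var in ["dbp", "log_ntprobnp", "nyha_iv"] + FOCAL_VARIABLES:
        try:
            X = _design(cohort, [var]).iloc[:, 0]
            mask = X.notna() & cohort[outcome].notna()
            roc_single[var] = roc_analysis(X[mask], cohort.loc[mask, outcome])
        except (ValueError, KeyError):
            continue

    combined_terms: list[LogisticResult] = []
    combined_roc = None
    try:
        combined_terms, probs = combined_model(cohort, outcome=outcome)
        if probs.notna().all() and len(probs):
            combined_roc = roc_analysis(
                probs.to_numpy(), cohort.loc[probs.index, outcome].to_numpy()
            )
    except (ValueError, KeyError):
        pass

    return StatReport(
        group_comparisons=comparisons,
        univariate=univariate,
        adjusted=adjusted,
        combined_terms=combined_terms,
        combined_roc=combined_roc,
        roc_single=roc_single,
        n_subjects=n_subjects,
        n_complete=n_complete,
    )
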