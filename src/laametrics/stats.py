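"""Statistical stage: univariate group tests, stepwise-AIC logistic
models, and random-forest importance for case/control stratification.

The protocol mirrors common clinical-cohort practice: continuous features
are tested with a pooled-variance Student t-test when both groups pass a
Shapiro-Wilk normality gate (alpha 0.05) and with a two-sided
Mann-Whitney U otherwise; categorical features use a chi-squared test
without continuity correction. Features significant at alpha become
candidates for a bidirectional stepwise logistic regression minimizing
AIC, run once with morphological candidates only and once jointly with
haemodynamic indices, so the added predictive value of the flow indices
shows up as an AIC drop. A 500-tree random forest (4 variables per
split, at most 90 terminal nodes) provides Gini importances and an
out-of-bag accuracy as a model-free cross-check.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .io import CohortTable

__all__ = [
    "TestResult", "ModelReport", "univariate_tests", "t_test_from_summary",
    "stepwise_logistic", "joint_model_comparison", "random_forest_importance",
]

ALPHA = 0.05


@dataclasses.dataclass
class TestResult:
    feature: str
    test_used: str            # student_t | mann_whitney | chi_squared
    statistic: float
    p_value: float
    summary: dict             # per-group summary, style matching the test
    significant: bool

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclasses.dataclass
class ModelReport:
    selected_features: list
    coefficients: dict
    aic: float
    aic_comparison: dict | None = None     # {"morphology": .., "joint": ..}
    rf_importances: dict | None = None
    rf_accuracy: float | None = None
    separation_flag: bool = False
    notes: list = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def _is_categorical(series: pd.Series) -> bool:
    return (series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype)
            or series.dtype == bool)


def univariate_tests(cohort: CohortTable, alpha: float = ALPHA,
                     use_welch: bool = False,
                     yates_correction: bool = False,
                     bh_correction: bool = False) -> list[TestResult]:
    """Per-feature two-group comparisons with automatic test selection.

    Continuous features: Shapiro-Wilk in each group at 0.05; both normal
    => Student t-test (pooled variance unless ``use_welch``), otherwise
    two-sided Mann-Whitney U (normal approximation with tie correction
    for n > 20, exact for small untied samples). Categorical features:
    chi-squared on the contingency table (no continuity correction by
    default). Summaries follow the normality outcome: mean +- SD for
    normal, median (min-max) otherwise, count (%) for categorical.
    No multiple-testing correction is applied unless ``bh_correction``.
    """
    cohort.validate()
    (g1, d1), (g2, d2) = cohort.groups()
    results: list[TestResult] = []
    for feat in cohort.feature_names:
        s1, s2 = d1[feat].dropna(), d2[feat].dropna()
        if _is_categorical(cohort.data[feat]):
            table = pd.crosstab(cohort.data[cohort.group_col],
                                cohort.data[feat])
            if table.shape[1] < 2:
                warnings.warn(f"{feat}: constant categorical feature, skipped")
                continue
            chi2, p, _, _ = sps.chi2_contingency(
                table.to_numpy(), correction=yates_correction)
            summary = {
                str(g): {str(k): f"{v} ({100 * v / len(d):.1f}%)"
                         for k, v in d[feat].value_counts().items()}
                for g, d in ((g1, d1), (g2, d2))
            }
            results.append(TestResult(feat, "chi_squared", float(chi2),
                                      float(p), summary, p < alpha))
            continue
        if len(s1) < 3 or len(s2) < 3:
            warnings.warn(f"{feat}: fewer than 3 values per group, skipped")
            continue
        if s1.nunique() < 2 or s2.nunique() < 2:
            warnings.warn(f"{feat}: constant feature, skipped")
            continue
        normal = (sps.shapiro(s1).pvalue > 0.05
                  and sps.shapiro(s2).pvalue > 0.05)
        if normal:
            t, p = sps.ttest_ind(s1, s2, equal_var=not use_welch)
            summary = {str(g): f"{s.mean():.2f} +- {s.std(ddof=1):.2f}"
                       for g, s in ((g1, s1), (g2, s2))}
            results.append(TestResult(feat, "student_t", float(t), float(p),
                                      summary, p < alpha))
        else:
            exact_ok = (len(s1) <= 20 and len(s2) <= 20
                        and not _has_ties(s1, s2))
            u, p = sps.mannwhitneyu(
                s1, s2, alternative="two-sided",
                method="exact" if exact_ok else "asymptotic",
                use_continuity=False)
            summary = {str(g): f"{s.median():.2f} ({s.min():.2f}-{s.max():.2f})"
                       for g, s in ((g1, s1), (g2, s2))}
            results.append(TestResult(feat, "mann_whitney", float(u), float(p),
                                      summary, p < alpha))
    if bh_correction:
        ps = np.array([r.p_value for r in results])
        from statsmodels.stats.multitest import multipletests

        rej, p_adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
        for r, pa, rj in zip(results, p_adj, rej):
            r.p_value, r.significant = float(pa), bool(rj)
    return results


def _has_ties(s1, s2) -> bool:
    pooled = np.concatenate([s1.to_numpy(float), s2.to_numpy(float)])
    return len(np.unique(pooled)) < len(pooled)


def t_test_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance two-sided Student t-test from printed summaries.

    Returns (t, df, p); useful for checking published group tables where
    only mean +- SD per group is available.
    """
    if min(sd1, sd2) <= 0 or min(n1, n2) < 2:
        raise ValueError("need sds > 0 and ns >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


# ---------------------------------------------------------------------------
# stepwise logistic regression
# ---------------------------------------------------------------------------

def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """GLM binomial/logit fit; returns (aic, params, separation_flag)."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)
        except Exception:
            return np.inf, {}, True
        mu = np.asarray(fit.fittedvalues)
        separated = bool(np.any((mu < 1e-8) | (mu > 1 - 1e-8))) \
            or not np.all(np.isfinite(fit.bse))
        return float(fit.aic), dict(fit.params), separated


def stepwise_logistic(cohort: CohortTable, candidate_features: list[str],
                      direction: str = "both") -> ModelReport:
    """Bidirectional stepwise logistic regression minimizing AIC.

    Starts from the model containing all candidates and repeatedly applies
    the single add/drop move that lowers AIC most, until no move improves
    it (AIC = -2 logLik + 2k, counting the intercept). Perfect separation
    is reported via a flag; the coefficients of a separated model should
    not be interpreted.
    """
    cohort.validate()
    candidates = list(dict.fromkeys(candidate_features))
    if len(candidates) < len(candidate_features):
        warnings.warn("duplicate candidate features removed")
    data = cohort.data.dropna(subset=candidates)
    levels = sorted(data[cohort.group_col].unique())
    y = (data[cohort.group_col] == levels[1]).to_numpy(int)
    X_all = data[candidates].astype(float)

    current = list(candidates)
    best_aic, params, sep = _fit_logit(X_all[current], y)
    while True:
        moves = []
        if direction in ("both", "backward"):
            moves += [("drop", f) for f in current]
        if direction in ("both", "forward"):
            moves += [("add", f) for f in candidates if f not in current]
        best_move = None
        for kind, f in moves:
            trial = ([c for c in current if c != f] if kind == "drop"
                     else current + [f])
            aic, _, _ = _fit_logit(X_all[trial], y) if trial else \
                _fit_logit(X_all[[]], y)
            if aic < best_aic - 1e-9:
                if best_move is None or aic < best_move[0]:
                    best_move = (aic, kind, f)
        if best_move is None:
            break
        best_aic, kind, f = best_move
        current = ([c for c in current if c != f] if kind == "drop"
                   else current + [f])
    best_aic, params, sep = _fit_logit(X_all[current], y)
    return ModelReport(selected_features=current, coefficients=params,
                       aic=best_aic, separation_flag=sep)


def joint_model_comparison(cohort: CohortTable, morph_features: list[str],
                           haemo_features: list[str]) -> ModelReport:
    """Morphology-only vs morphology+haemodynamics stepwise models.

    Both stepwise fits run on the identical subject set (rows complete in
    all features), so the AIC difference isolates the value added by the
    haemodynamic indices. Features listed in both blocks are deduplicated
    with a warning.
    """
    overlap = set(morph_features) & set(haemo_features)
    if overlap:
        warnings.warn(f"features in both blocks deduplicated: {sorted(overlap)}")
        haemo_features = [f for f in haemo_features if f not in overlap]
    all_feats = list(morph_features) + list(haemo_features)
    complete = cohort.data.dropna(subset=all_feats)
    if len(complete) < len(cohort.data):
        missing = len(cohort.data) - len(complete)
        if set(cohort.data.dropna(subset=morph_features).index) != \
                set(cohort.data.dropna(subset=all_feats).index):
            raise ValueError(
                f"subject sets differ between feature blocks ({missing} "
                "subjects lack haemodynamic values); harmonize first")
    sub = CohortTable(complete, cohort.group_col)
    morph = stepwise_logistic(sub, morph_features)
    joint = stepwise_logistic(sub, all_feats)
    joint.aic_comparison = {
        "morphology": morph.aic, "joint": joint.aic,
        "delta": joint.aic - morph.aic,
    }
    joint.notes.append(
        f"morphology-only model selected {morph.selected_features}")
    return joint


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def random_forest_importance(cohort: CohortTable, features: list[str],
                             n_trees: int = 500, mtry: int = 4,
                             max_nodes: int = 90,
                             seed: int = 0) -> ModelReport:
    """Classification forest with Gini importances and out-of-bag accuracy.

    Defaults follow the grid-searched hyperparameters used for this kind
    of cohort: 500 trees, 4 variables sampled at each split, at most 90
    terminal nodes. Categorical features (e.g. the shape label) are
    integer-encoded. Importances are mean decrease in Gini impurity.
    """
    cohort.validate()
    data = cohort.data.dropna(subset=features)
    if len(data) < 10:
        raise ValueError("need at least 10 complete subjects for the forest")
    X = pd.DataFrame(index=data.index)
    for f in features:
        col = data[f]
        X[f] = (pd.Categorical(col).codes if _is_categorical(col)
                else col.astype(float))
    levels = sorted(data[cohort.group_col].unique())
    y = (data[cohort.group_col] == levels[1]).to_numpy(int)
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features=min(mtry, len(features)),
        max_leaf_nodes=max_nodes, oob_score=True, random_state=seed,
        n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # small-n OOB coverage warnings
        rf.fit(X.to_numpy(), y)
    importances = dict(zip(features, rf.feature_importances_))
    return ModelReport(
        selected_features=sorted(importances, key=importances.get,
                                 reverse=True),
        coefficients={}, aic=float("nan"),
        rf_importances=importances, rf_accuracy=float(rf.oob_score_))
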