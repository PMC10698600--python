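"""Severity classification and indicator regression with nested CV.

Feature groups follow the study design: L (the 78 lung features), P
(patient attributes: gestational age, birth weight, body size, sex) and C
(postnatal adaptation: 5-minute Apgar, early-onset infection, steroid
treatment), combined into designs such as GA, L, PC or PCL.

Model selection is a randomized hyperparameter search on inner stratified
5-fold splits nested strictly inside each outer training fold; scaling
and dimensionality reduction are part of the searched pipeline, so no
statistic of an outer test fold ever reaches the fit.  Performance is the
AUC of the pooled outer-fold predictions per repetition (macro
prevalence-weighted one-vs-rest for the 4-class scenario), reported as
mean +/- SD across repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import SelectKBest, f_classif, f_regression
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LogisticRegression, PoissonRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .manifest import FEATURE_NAMES
from .phantom import C_COLUMNS, P_COLUMNS

logger = logging.getLogger(__name__)

GROUPS: dict[str, tuple[str, ...]] = {
    "L": tuple(FEATURE_NAMES),
    "P": P_COLUMNS,
    "C": C_COLUMNS,
}

SCENARIOS = ("binary_any", "binary_moderate_severe", "multinomial")


def _scenario_labels(grade: np.ndarray, scenario: str) -> np.ndarray:
    if scenario == "binary_any":           # no disease vs any grade
        return (grade > 0).astype(int)
    if scenario == "binary_moderate_severe":  # none/mild vs moderate/severe
        return (grade >= 2).astype(int)
    if scenario == "multinomial":
        return grade.astype(int)
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def selector_columns(selector: str) -> list[str]:
    """Resolve a group selector ('GA', 'L', 'PC', 'PCL', ...) to columns."""
    if selector == "GA":
        return ["gestational_age_wk"]
    cols: list[str] = []
    for letter in selector:
        if letter not in GROUPS:
            raise ValueError(f"unknown group letter {letter!r} in selector {selector!r}")
        cols.extend(GROUPS[letter])
    if not cols:
        raise ValueError("empty selector")
    return cols


def build_design(
    cohort: pd.DataFrame, selector: str, label_column: str = "grade"
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and label vector for a group selector.

    Subjects with missing values in the selected columns are excluded
    with a logged count; all-constant columns are dropped with a warning.
    Columns are returned unscaled — standardisation is fitted on training
    folds only, inside the CV pipeline.
    """
    cols = selector_columns(selector)
    missing = [c for c in cols + [label_column] if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing[:5]}")
    sub = cohort[cols + [label_column]]
    complete = sub.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("excluded %d subject(s) with missing values", n_excluded)
    sub = sub.loc[complete]
    X = sub[cols].astype(float)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.warning("dropping all-constant column(s): %s", constant[:5])
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("empty design after dropping constant columns")
    return X, sub[label_column]


@dataclass
class CVPlan:
    """Nested stratified CV layout: 5 outer x 5 inner folds, 10 repetitions."""

    outer_folds: int = 5
    inner_folds: int = 5
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.outer_folds, self.inner_folds) < 2 or self.repetitions < 1:
            raise ValueError("folds must be >= 2 and repetitions >= 1")


@dataclass
class ScenarioResult:
    """Nested-CV outcome of one scenario/model/reduction combination."""

    scenario: str
    model_family: str
    reduction: str
    per_repetition_auc: list[float]
    per_repetition_auc_unweighted: list[float]
    per_class_auc: dict[int, float]
    best_params: list[dict] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_repetition_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.per_repetition_auc, ddof=1)) if len(self.per_repetition_auc) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "model_family": self.model_family,
            "reduction": self.reduction,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_auc_unweighted": float(np.mean(self.per_repetition_auc_unweighted)),
            "per_class_auc": {int(k): float(v) for k, v in self.per_class_auc.items()},
            "n_repetitions": len(self.per_repetition_auc),
        }


def _classifier_search_space(model_family: str, n_features: int, reduction: str, rng_seed: int):
    if model_family == "elasticnet_logistic":
        est = LogisticRegression(
            penalty="elasticnet", solver="saga", max_iter=1000, tol=1e-3,
            random_state=rng_seed,
        )
        space = {
            "model__C": stats.loguniform(1e-2, 1e1),
            "model__l1_ratio": stats.uniform(0.0, 1.0),
        }
    elif model_family == "random_forest":
        est = RandomForestClassifier(random_state=rng_seed, n_jobs=1)
        space = {
            "model__n_estimators": stats.randint(50, 301),
            "model__max_depth": [None, 3, 5, 10, 20],
            "model__max_features": ["sqrt", "log2", 0.3, 0.6],
            "model__min_samples_leaf": stats.randint(1, 11),
        }
    else:
        raise ValueError(f"unknown model family {model_family!r}")
    steps = [("scale", StandardScaler())]
    if reduction == "univariate":
        steps.append(("reduce", SelectKBest(f_classif)))
        space["reduce__k"] = stats.randint(1, max(2, n_features))
    elif reduction == "pca":
        steps.append(("reduce", PCA(random_state=rng_seed)))
        space["reduce__n_components"] = stats.randint(1, max(2, min(n_features, 30)))
    elif reduction != "none":
        raise ValueError(f"unknown reduction {reduction!r}")
    steps.append(("model", est))
    return Pipeline(steps), space


def _pooled_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray):
    """(prevalence-weighted ovr AUC, unweighted ovr AUC, per-class dict)."""
    if len(classes) == 2:
        auc = roc_auc_score(y_true, proba[:, 1])
        return auc, auc, {int(classes[1]): auc}
    per_class, weights = {}, {}
    for i, c in enumerate(classes):
        ind = (y_true == c).astype(int)
        per_class[int(c)] = roc_auc_score(ind, proba[:, i])
        weights[int(c)] = ind.mean()
    unweighted = float(np.mean(list(per_class.values())))
    weighted = float(sum(per_class[c] * weights[c] for c in per_class) / sum(weights.values()))
    return weighted, unweighted, per_class


def nested_cv_classify(
    X,
    y,
    scenario: str = "binary_any",
    model_family: str = "random_forest",
    reduction: str = "none",
    plan: CVPlan | None = None,
    n_search: int = 50,
) -> ScenarioResult:
    """Nested-CV classification of one scenario.

    Hyperparameters (and the reduction's dimensionality) are selected by
    randomized search (``n_search`` draws) on inner folds only; outer-fold
    predicted probabilities are pooled per repetition and scored with the
    AUC (macro prevalence-weighted one-vs-rest when multiclass).
    """
    plan = plan or CVPlan()
    X = np.asarray(X, dtype=float)
    grade = np.asarray(y)
    labels = _scenario_labels(grade, scenario)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes present")

    per_rep_w, per_rep_u, best_params = [], [], []
    class_accum: dict[int, list[float]] = {int(c): [] for c in classes}
    for rep in range(plan.repetitions):
        rep_seed = plan.seed * 1000 + rep
        outer = StratifiedKFold(plan.outer_folds, shuffle=True, random_state=rep_seed)
        pooled_proba = np.zeros((len(labels), len(classes)))
        for k, (tr, te) in enumerate(outer.split(X, labels)):
            if len(np.unique(labels[tr])) < len(classes):
                raise ValueError("a class is absent from an outer training fold")
            pipe, space = _classifier_search_space(
                model_family, X.shape[1], reduction, rep_seed + k
            )
            inner = StratifiedKFold(plan.inner_folds, shuffle=True, random_state=rep_seed + k)
            scoring = "roc_auc" if len(classes) == 2 else "roc_auc_ovr_weighted"
            search = RandomizedSearchCV(
                pipe,
                space,
                n_iter=n_search,
                cv=inner,
                scoring=scoring,
                random_state=rep_seed + k,
                n_jobs=1,
            )
            search.fit(X[tr], labels[tr])
            pooled_proba[te] = search.predict_proba(X[te])
            best_params.append(search.best_params_)
        w, u, per_class = _pooled_auc(labels, pooled_proba, classes)
        per_rep_w.append(w)
        per_rep_u.append(u)
        for c, v in per_class.items():
            class_accum[c].append(v)
    return ScenarioResult(
        scenario=scenario,
        model_family=model_family,
        reduction=reduction,
        per_repetition_auc=per_rep_w,
        per_repetition_auc_unweighted=per_rep_u,
        per_class_auc={c: float(np.mean(v)) for c, v in class_accum.items()},
        best_params=best_params,
    )


def nested_cv_regress(
    X,
    counts,
    model_family: str = "poisson",
    reduction: str = "none",
    plan: CVPlan | None = None,
    n_search: int = 50,
) -> dict:
    """Nested-CV regression of a non-negative count indicator; the metric
    is the mean absolute error of pooled outer-fold predictions per
    repetition."""
    plan = plan or CVPlan()
    X = np.asarray(X, dtype=float)
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise ValueError("count responses must be non-negative")

    if model_family == "poisson":
        est = PoissonRegressor(max_iter=2000)
        space = {"model__alpha": stats.loguniform(1e-4, 1e2)}
    elif model_family == "random_forest":
        est = RandomForestRegressor(random_state=plan.seed, n_jobs=1)
        space = {
            "model__n_estimators": stats.randint(50, 301),
            "model__max_depth": [None, 3, 5, 10, 20],
            "model__min_samples_leaf": stats.randint(1, 11),
        }
    else:
        raise ValueError(f"unknown model family {model_family!r}")

    maes = []
    # stratify outer folds on the quartile bin of the response
    bins = np.searchsorted(np.quantile(y, [0.25, 0.5, 0.75]), y)
    for rep in range(plan.repetitions):
        rep_seed = plan.seed * 1000 + rep
        outer = StratifiedKFold(plan.outer_folds, shuffle=True, random_state=rep_seed)
        pooled = np.zeros_like(y)
        for k, (tr, te) in enumerate(outer.split(X, bins)):
            steps = [("scale", StandardScaler())]
            sp = dict(space)
            if reduction == "univariate":
                steps.append(("reduce", SelectKBest(f_regression)))
                sp["reduce__k"] = stats.randint(1, max(2, X.shape[1]))
            elif reduction == "pca":
                steps.append(("reduce", PCA(random_state=rep_seed + k)))
                sp["reduce__n_components"] = stats.randint(1, max(2, min(X.shape[1], 30)))
            steps.append(("model", est))
            search = RandomizedSearchCV(
                Pipeline(steps),
                sp,
                n_iter=n_search,
                cv=plan.inner_folds,
                scoring="neg_mean_absolute_error",
                random_state=rep_seed + k,
                n_jobs=1,
            )
            search.fit(X[tr], y[tr])
            pooled[te] = search.predict(X[te])
        maes.append(float(np.mean(np.abs(pooled - y))))
    return {
        "model_family": model_family,
        "reduction": reduction,
        "per_repetition_mae": maes,
        "mean_mae": float(np.mean(maes)),
        "sd_mae": float(np.std(maes, ddof=1)) if len(maes) > 1 else 0.0,
    }


def permutation_importance(
    fitted_model, X, y, n_repeats: int = 100, seed: int = 0, scoring: str = "roc_auc"
) -> pd.DataFrame:
    """Mean AUC drop per permuted column on held-out data, ranked."""
    X = np.asarray(X, dtype=float)
    result = _sk_permutation_importance(
        fitted_model, X, np.asarray(y), n_repeats=n_repeats, random_state=seed, scoring=scoring
    )
    frame = pd.DataFrame(
        {
            "importance_mean": result.importances_mean,
            "importance_sd": result.importances_std,
        }
    )
    frame["rank"] = frame["importance_mean"].rank(ascending=False).astype(int)
    if X.shape[1] == 1:
        frame.attrs["note"] = "single-column design: importance is trivially the full score drop"
    return frame.sort_values("importance_mean", ascending=False)


def feature_correlation_matrix(
    table: pd.DataFrame, feature_cols: list[str], target_cols: list[str], alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Pairwise Spearman correlations with Bonferroni-adjusted significance.

    Returns ``r``, ``p`` and boolean ``significant`` matrices (features x
    targets); cells involving a constant column are NaN / flagged False.
    """
    n_tests = len(feature_cols) * len(target_cols)
    adj_alpha = alpha / max(n_tests, 1)
    r = pd.DataFrame(index=feature_cols, columns=target_cols, dtype=float)
    p = pd.DataFrame(index=feature_cols, columns=target_cols, dtype=float)
    for f in feature_cols:
        for t in target_cols:
            pair = table[[f, t]].dropna()
            if len(pair) < 3 or pair[f].nunique() <= 1 or pair[t].nunique() <= 1:
                r.loc[f, t] = np.nan
                p.loc[f, t] = np.nan
                continue
            rho, pval = stats.spearmanr(pair[f], pair[t])
            r.loc[f, t] = rho
            p.loc[f, t] = pval
    significant = p < adj_alpha
    significant[p.isna()] = False
    return {"r": r, "p": p, "significant": significant, "adjusted_alpha": adj_alpha}


def kruskal_by_group(table: pd.DataFrame, value_col: str, group_col: str = "grade") -> dict:
    """Kruskal-Wallis H test of a column across severity grades."""
    groups = [g[value_col].dropna().values for _, g in table.groupby(group_col)]
    groups = [g for g in groups if len(g) > 0]
    stat, pval = stats.kruskal(*groups)
    return {"H": float(stat), "p": float(pval), "n_groups": len(groups)}


def pairwise_mannwhitney(
    table: pd.DataFrame, value_col: str, group_col: str = "grade", alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise Mann-Whitney U tests with Bonferroni correction."""
    keys = sorted(table[group_col].dropna().unique())
    rows = []
    pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]]
    for a, b in pairs:
        u, pval = stats.mannwhitneyu(
            table.loc[table[group_col] == a, value_col].dropna(),
            table.loc[table[group_col] == b, value_col].dropna(),
            alternative="two-sided",
        )
        rows.append({"group_a": a, "group_b": b, "U": float(u), "p": float(pval)})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(pairs), 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
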