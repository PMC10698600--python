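"""Design construction, nested-CV discipline, AUC recovery, importance and
correlation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from neolung.manifest import FEATURE_NAMES
from neolung.models import (
    CVPlan,
    build_design,
    feature_correlation_matrix,
    kruskal_by_group,
    nested_cv_classify,
    nested_cv_regress,
    pairwise_mannwhitney,
    permutation_importance,
    selector_columns,
)
from neolung.phantom import CohortSpec, generate_cohort

PLANTED = {name: 2.0 for name in FEATURE_NAMES[:5]}


@pytest.fixture(scope="module")
def null_cohort():
    return generate_cohort(CohortSpec(n_subjects=200, seed=42))


@pytest.fixture(scope="module")
def planted_cohort():
    return generate_cohort(CohortSpec(n_subjects=200, effect_sizes=PLANTED, seed=42))


class TestBuildDesign:
    def test_ga_selector_is_single_column(self, null_cohort):
        X, y = build_design(null_cohort, "GA")
        assert list(X.columns) == ["gestational_age_wk"]
        assert len(y) == len(X) == 200

    def test_pcl_selector_column_count(self, null_cohort):
        X, _ = build_design(null_cohort, "PCL")
        assert X.shape[1] == 4 + 3 + 78

    def test_missing_values_excluded_with_count(self, null_cohort, caplog):
        cohort = null_cohort.copy()
        cohort.loc[cohort.index[:4], "apgar5"] = np.nan
        with caplog.at_level("INFO", logger="neolung.models"):
            X, y = build_design(cohort, "PC")
        assert len(X) == 196
        assert "4 subject" in caplog.text

    def test_constant_column_dropped_with_warning(self, null_cohort, caplog):
        cohort = null_cohort.copy()
        cohort["steroid_treatment"] = 0
        with caplog.at_level("WARNING", logger="neolung.models"):
            X, _ = build_design(cohort, "C")
        assert "steroid_treatment" not in X.columns

    def test_unknown_selector_rejected(self, null_cohort):
        with pytest.raises(ValueError, match="unknown group"):
            build_design(null_cohort, "PX")

    def test_design_is_unscaled_raw_data(self, null_cohort):
        # scaling belongs to the CV pipeline (train folds only), so the
        # returned matrix keeps raw units
        X, _ = build_design(null_cohort, "P")
        assert X["birth_weight_g"].mean() > 100


FAST_PLAN = CVPlan(repetitions=3, seed=0)


class TestNestedCVClassify:
    def test_null_features_give_chance_auc(self, null_cohort):
        X, y = build_design(null_cohort, "L")
        result = nested_cv_classify(
            X, y, scenario="binary_any", model_family="elasticnet_logistic",
            plan=FAST_PLAN, n_search=4,
        )
        assert 0.40 <= result.mean_auc <= 0.60

    def test_planted_effect_recovered(self, planted_cohort):
        X, y = build_design(planted_cohort, "L")
        result = nested_cv_classify(
            X, y, scenario="binary_any", model_family="elasticnet_logistic",
            plan=FAST_PLAN, n_search=4,
        )
        assert result.mean_auc >= 0.9

    def test_perfect_separator_gives_auc_one(self, null_cohort):
        X, y = build_design(null_cohort, "L")
        X = X.copy()
        X["sep"] = (np.asarray(y) > 0).astype(float)
        result = nested_cv_classify(
            X, y, scenario="binary_any", model_family="random_forest",
            plan=CVPlan(repetitions=1, seed=0), n_search=2,
        )
        assert result.mean_auc == pytest.approx(1.0, abs=1e-9)

    def test_multinomial_macro_weighting_balanced_equals_mean(self):
        # balanced classes: the prevalence-weighted one-vs-rest AUC equals
        # the unweighted mean
        cohort = generate_cohort(
            CohortSpec(
                n_subjects=120,
                class_proportions=(0.25, 0.25, 0.25, 0.25),
                effect_sizes=PLANTED,
                seed=7,
            )
        )
        X, y = build_design(cohort, "L")
        result = nested_cv_classify(
            X, y, scenario="multinomial", model_family="elasticnet_logistic",
            plan=CVPlan(repetitions=2, seed=1), n_search=3,
        )
        w = np.asarray(result.per_repetition_auc)
        u = np.asarray(result.per_repetition_auc_unweighted)
        assert np.allclose(w, u, atol=0.01)
        assert len(result.per_class_auc) == 4

    def test_reproducible_given_seeds(self, planted_cohort):
        X, y = build_design(planted_cohort, "L")
        kw = dict(
            scenario="binary_moderate_severe", model_family="elasticnet_logistic",
            plan=CVPlan(repetitions=2, seed=5), n_search=3,
        )
        r1 = nested_cv_classify(X, y, **kw)
        r2 = nested_cv_classify(X, y, **kw)
        assert r1.per_repetition_auc == r2.per_repetition_auc

    def test_naive_full_data_selection_inflates_auc_but_nested_cv_does_not(self):
        # leakage canary: selecting features on the full data before CV is
        # the classic leak; the nested pipeline must not show this lift
        rng = np.random.default_rng(0)
        n, p = 60, 300
        X = rng.normal(size=(n, p))
        y = rng.integers(0, 2, size=n)

        naive_sel = SelectKBest(f_classif, k=10).fit(X, y)  # sees all labels
        Xs = naive_sel.transform(X)
        pooled = np.zeros(n)
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(Xs, y):
            clf = LogisticRegression(max_iter=1000).fit(Xs[tr], y[tr])
            pooled[te] = clf.predict_proba(Xs[te])[:, 1]
        naive_auc = roc_auc_score(y, pooled)

        result = nested_cv_classify(
            X, y, scenario="binary_any", model_family="elasticnet_logistic",
            reduction="univariate", plan=CVPlan(repetitions=1, seed=0), n_search=3,
        )
        assert naive_auc > 0.75  # the leak is real on noise
        assert result.mean_auc < 0.65  # our nested CV does not inherit it

    def test_missing_class_in_training_fold_raises(self):
        X = pd.DataFrame({"f": np.arange(12, dtype=float)})
        y = np.array([0] * 11 + [1])  # the lone positive starves its training fold
        with pytest.raises(ValueError):
            nested_cv_classify(
                X, y, scenario="binary_any",
                plan=CVPlan(outer_folds=5, repetitions=1, seed=0), n_search=2,
            )


class TestNestedCVRegress:
    def test_negative_counts_rejected(self, null_cohort):
        X, _ = build_design(null_cohort, "GA")
        with pytest.raises(ValueError, match="non-negative"):
            nested_cv_regress(X, -np.ones(len(X)), plan=FAST_PLAN)

    def test_poisson_handles_overdispersed_counts(self, null_cohort):
        X, _ = build_design(null_cohort, "GA")
        out = nested_cv_regress(
            X, null_cohort["ventilation_days"], model_family="poisson",
            plan=CVPlan(repetitions=2, seed=0), n_search=3,
        )
        assert np.isfinite(out["mean_mae"])

    def test_lung_features_beat_ga_alone_on_linked_response(self, planted_cohort):
        # ventilation days are grade-linked, and grade shifts the planted
        # features, so the richer design should reduce MAE
        plan = CVPlan(repetitions=3, seed=2)
        y = planted_cohort["ventilation_days"]
        mae_ga = nested_cv_regress(
            build_design(planted_cohort, "GA")[0], y, model_family="random_forest",
            plan=plan, n_search=3,
        )["mean_mae"]
        mae_pcl = nested_cv_regress(
            build_design(planted_cohort, "PCL")[0], y, model_family="random_forest",
            plan=plan, n_search=3,
        )["mean_mae"]
        assert mae_pcl < mae_ga


class TestPermutationImportance:
    @pytest.fixture(scope="class")
    def fitted(self, planted_cohort):
        X, y = build_design(planted_cohort, "L")
        labels = (np.asarray(y) > 0).astype(int)
        model = LogisticRegression(max_iter=2000).fit(X.iloc[:150], labels[:150])
        return model, X.iloc[150:], labels[150:], list(X.columns)

    def test_planted_features_rank_highest(self, fitted):
        model, Xh, yh, cols = fitted
        imp = permutation_importance(model, Xh, yh, n_repeats=30, seed=0)
        top = set(imp.index[:5])
        planted_idx = {cols.index(n) for n in PLANTED}
        assert len(top & planted_idx) >= 3

    def test_noise_columns_have_near_zero_importance(self, fitted):
        model, Xh, yh, cols = fitted
        imp = permutation_importance(model, Xh, yh, n_repeats=100, seed=0)
        noise_idx = [i for i, n in enumerate(cols) if n not in PLANTED]
        assert np.abs(imp.loc[noise_idx, "importance_mean"]).median() < 0.02


class TestCorrelationAndGroups:
    def test_self_and_monotone_transform_correlation_is_one(self, null_cohort):
        col = FEATURE_NAMES[0]
        t = null_cohort[[col]].copy()
        t["same"] = t[col]
        t["exp"] = np.exp(t[col])  # monotone transform: identical ranks
        out = feature_correlation_matrix(t, [col], ["same", "exp"])
        assert out["r"].loc[col, "same"] == pytest.approx(1.0)
        assert out["r"].loc[col, "exp"] == pytest.approx(1.0)

    def test_hand_worked_six_point_table(self):
        # classic rank computation: d = [0,-1,1,0,0,0] -> rho = 1 - 6*2/(6*35)
        x = [1, 2, 3, 4, 5, 6]
        y = [1, 3, 2, 4, 5, 6]
        t = pd.DataFrame({"x": x, "y": y})
        out = feature_correlation_matrix(t, ["x"], ["y"])
        assert out["r"].loc["x", "y"] == pytest.approx(1 - 6 * 2 / (6 * 35))

    def test_bonferroni_threshold_applied(self, planted_cohort):
        feats = FEATURE_NAMES[:10]
        out = feature_correlation_matrix(planted_cohort, feats, ["grade", "ventilation_days"])
        assert out["adjusted_alpha"] == pytest.approx(0.05 / 20)
        # the planted features correlate with grade even after correction
        assert out["significant"].loc[FEATURE_NAMES[0], "grade"]

    def test_constant_column_flagged_not_crashed(self, null_cohort):
        t = null_cohort.copy()
        t["const"] = 1.0
        out = feature_correlation_matrix(t, ["const"], ["grade"])
        assert np.isnan(out["r"].loc["const", "grade"])
        assert not out["significant"].loc["const", "grade"]

    def test_kruskal_and_mannwhitney_on_planted_feature(self, planted_cohort):
        col = FEATURE_NAMES[0]
        kw = kruskal_by_group(planted_cohort, col)
        assert kw["p"] < 1e-6
        mw = pairwise_mannwhitney(planted_cohort, col)
        assert len(mw) == 6  # 4 choose 2
        assert mw["significant"].any()
        assert (mw["p_bonferroni"] >= mw["p"] - 1e-12).all()

    def test_selector_columns_cover_groups(self):
        assert selector_columns("PC") == [
            "gestational_age_wk", "birth_weight_g", "body_size_cm", "sex",
            "apgar5", "early_onset_infection", "steroid_treatment",
        ]
        assert len(selector_columns("PCL")) == 85
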