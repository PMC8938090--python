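"""Statistical stage: test selection, oracles, model selection, forest."""

import numpy as np
import pandas as pd
import pytest

from laametrics.io import CohortTable
from laametrics.stats import (joint_model_comparison,
                              random_forest_importance, stepwise_logistic,
                              t_test_from_summary, univariate_tests)


def _cohort(control: dict, case: dict) -> CohortTable:
    n1 = len(next(iter(control.values())))
    n2 = len(next(iter(case.values())))
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n1 + n2)],
        "group": ["control"] * n1 + ["case"] * n2,
        **{k: np.concatenate([np.asarray(v), np.asarray(case[k])])
           for k, v in control.items()},
    })
    return CohortTable(df)


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def test_test_selection_by_variable_nature():
    rng = np.random.default_rng(0)
    cohort = _cohort(
        {"normal_f": rng.normal(10, 2, 38),
         "skewed_f": rng.lognormal(1.0, 1.0, 38)},
        {"normal_f": rng.normal(11, 2, 33),
         "skewed_f": rng.lognormal(1.2, 1.0, 33)})
    cohort.data["shape"] = rng.choice(["cw", "non-cw"], len(cohort.data))
    by_feat = {r.feature: r for r in univariate_tests(cohort)}
    assert by_feat["normal_f"].test_used == "student_t"
    assert "+-" in list(by_feat["normal_f"].summary.values())[0]
    assert by_feat["skewed_f"].test_used == "mann_whitney"
    assert "(" in list(by_feat["skewed_f"].summary.values())[0]
    assert by_feat["shape"].test_used == "chi_squared"


def test_identical_groups_mann_whitney_p_is_one():
    vals = np.random.default_rng(1).lognormal(0, 1.5, 30)
    cohort = _cohort({"f": vals}, {"f": vals.copy()})
    res = univariate_tests(cohort)[0]
    assert res.test_used == "mann_whitney"
    assert res.p_value == pytest.approx(1.0, abs=1e-9)
    assert not res.significant


def test_constant_feature_skipped_with_warning():
    cohort = _cohort({"f": np.ones(10), "g": np.arange(10.0)},
                     {"f": np.ones(10), "g": np.arange(10.0) + 3})
    with pytest.warns(UserWarning, match="constant"):
        res = univariate_tests(cohort)
    assert [r.feature for r in res] == ["g"]


@pytest.mark.parametrize("m1,s1,n1,m2,s2,n2,p_expected", [
    (86.4, 15.9, 38, 78.5, 16.6, 33, 0.045),     # rounds to printed value
    (25.77, 4.40, 38, 30.20, 4.90, 33, 0.00015),
])
def test_t_from_summary_reproduces_printed_p(m1, s1, n1, m2, s2, n2,
                                             p_expected):
    t, df, p = t_test_from_summary(m1, s1, n1, m2, s2, n2)
    assert df == n1 + n2 - 2
    assert p == pytest.approx(p_expected, rel=0.05)


def test_t_from_summary_equal_groups():
    t, df, p = t_test_from_summary(5.0, 1.0, 20, 5.0, 1.0, 20)
    assert t == 0.0 and p == 1.0


def test_chi_squared_contingency_oracle():
    """2x2 gender-style table: statistic 5.93, p 0.015 uncorrected."""
    cohort = _cohort({"sex": ["f"] * 11 + ["m"] * 27},
                     {"sex": ["f"] * 19 + ["m"] * 14})
    res = univariate_tests(cohort)[0]
    assert res.statistic == pytest.approx(5.93, abs=0.01)
    assert res.p_value == pytest.approx(0.0149, abs=0.001)


def test_type_one_error_calibration():
    """Null rejection rate 0.05 +- 0.015 for both test branches."""
    rng = np.random.default_rng(2024)
    from scipy import stats as sps

    n1, n2, reps = 38, 33, 2000
    a = rng.normal(size=(reps, n1))
    b = rng.normal(size=(reps, n2))
    rej_t = np.mean(sps.ttest_ind(a, b, axis=1).pvalue < 0.05)
    rej_u = np.mean([
        sps.mannwhitneyu(a[i], b[i], alternative="two-sided",
                         method="asymptotic", use_continuity=False).pvalue
        < 0.05 for i in range(reps)])
    assert abs(rej_t - 0.05) < 0.015
    assert abs(rej_u - 0.05) < 0.015


# ---------------------------------------------------------------------------
# stepwise logistic
# ---------------------------------------------------------------------------

def test_intercept_only_aic_closed_form():
    rng = np.random.default_rng(3)
    cohort = _cohort({"x": rng.normal(size=15)}, {"x": rng.normal(size=15)})
    rep = stepwise_logistic(cohort, ["x"])
    # balanced n=30 null: logLik = 30 ln(1/2), AIC = -2 logLik + 2
    if not rep.selected_features:
        assert rep.aic == pytest.approx(-2 * 30 * np.log(0.5) + 2, abs=1e-6)
    else:   # x kept only if it lowered AIC below the intercept-only value
        assert rep.aic < -2 * 30 * np.log(0.5) + 2


def test_stepwise_recovers_planted_signal():
    hits = 0
    reps = 30
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        n = 200
        x_true = rng.normal(size=n)
        noise = rng.normal(size=(n, 5))
        logits = 2.0 * x_true
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-logits))
        df = pd.DataFrame(noise, columns=[f"n{i}" for i in range(5)])
        df["signal"] = x_true
        df["group"] = np.where(y, "case", "control")
        df["subject_id"] = [f"s{i}" for i in range(n)]
        if (df["group"] == "case").nunique() == 1:
            continue
        rep = stepwise_logistic(CohortTable(df),
                                ["signal"] + [f"n{i}" for i in range(5)])
        hits += "signal" in rep.selected_features
    assert hits >= 0.9 * reps


def test_stepwise_all_noise_prefers_small_models():
    kept = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 120
        df = pd.DataFrame(rng.normal(size=(n, 4)),
                          columns=["a", "b", "c", "d"])
        df["group"] = np.repeat(["control", "case"], n // 2)
        df["subject_id"] = [f"s{i}" for i in range(n)]
        rep = stepwise_logistic(CohortTable(df), ["a", "b", "c", "d"])
        kept.append(len(rep.selected_features))
    # pure-noise candidates: the intercept-only model wins most replicates
    assert np.median(kept) == 0


def test_joint_comparison_dedup_and_no_spurious_gain():
    deltas = []
    for seed in range(8):
        rng = np.random.default_rng(seed)
        n = 120
        x = rng.normal(size=n)
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-1.5 * x))
        df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)],
                           "group": np.where(y, "case", "control"),
                           "m1": x, "m2": rng.normal(size=n),
                           "h1": rng.normal(size=n), "h2": rng.normal(size=n)})
        cohort = CohortTable(df)
        with pytest.warns(UserWarning, match="deduplicated"):
            rep = joint_model_comparison(cohort, ["m1", "m2"],
                                         ["m1", "h1", "h2"])
        cmp_ = rep.aic_comparison
        assert cmp_["delta"] == pytest.approx(cmp_["joint"]
                                              - cmp_["morphology"])
        deltas.append(cmp_["delta"])
    # pure-noise haemodynamic block: no large spurious AIC gain on average
    # (a single replicate can draw a lucky chi-square improvement)
    assert np.mean(deltas) >= -3.0


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def _planted_forest_cohort(seed, n=300):
    rng = np.random.default_rng(seed)
    informative = rng.integers(0, 2, n)
    noise = rng.normal(size=(n, 9))
    df = pd.DataFrame(noise, columns=[f"n{i}" for i in range(9)])
    df["marker"] = informative.astype(float)
    df["group"] = np.where(
        rng.uniform(size=n) < np.where(informative, 0.9, 0.1),
        "case", "control")
    df["subject_id"] = [f"s{i}" for i in range(n)]
    return CohortTable(df)


def test_forest_ranks_planted_feature_first():
    cohort = _planted_forest_cohort(0)
    rep = random_forest_importance(
        cohort, ["marker"] + [f"n{i}" for i in range(9)], seed=1)
    assert rep.selected_features[0] == "marker"
    assert rep.rf_importances["marker"] == max(rep.rf_importances.values())
    assert 0.0 <= rep.rf_accuracy <= 1.0


def test_forest_seed_determinism():
    cohort = _planted_forest_cohort(1)
    feats = ["marker"] + [f"n{i}" for i in range(9)]
    r1 = random_forest_importance(cohort, feats, seed=11)
    r2 = random_forest_importance(cohort, feats, seed=11)
    assert r1.rf_importances == r2.rf_importances
    assert r1.rf_accuracy == r2.rf_accuracy


def test_forest_all_noise_oob_near_chance():
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(300 + seed)
        n = 300
        df = pd.DataFrame(rng.normal(size=(n, 10)),
                          columns=[f"n{i}" for i in range(10)])
        df["group"] = np.repeat(["control", "case"], n // 2)
        df["subject_id"] = [f"s{i}" for i in range(n)]
        rep = random_forest_importance(CohortTable(df),
                                       [f"n{i}" for i in range(10)],
                                       seed=seed)
        accs.append(rep.rf_accuracy)
    assert all(0.4 <= a <= 0.6 for a in accs)


def test_forest_needs_enough_subjects():
    cohort = _cohort({"x": np.arange(3.0)}, {"x": np.arange(3.0)})
    with pytest.raises(ValueError, match="10"):
        random_forest_importance(cohort, ["x"])
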