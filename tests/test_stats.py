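"""Behavioral summaries and the statistical battery."""

import numpy as np
import pandas as pd
import pytest

from rlwm.stats import (age_trend, anova_by_factor, apply_exclusion, cohens_d,
                        compare_groups, logistic_age_classifier,
                        parameter_correlation_matrix, rt_parameter_regression,
                        speed_accuracy_analysis, summaries_frame,
                        summarize_subject)
from rlwm.task import SubjectDataset


def _dataset(subject_id="s", rewards=(1, 1, 1, 1, 0, 0), rts=600.0,
             set_sizes=None, group=None, age=None, moca=None):
    n = len(rewards)
    set_sizes = set_sizes or [2] * n
    df = pd.DataFrame({
        "subject_id": subject_id, "block": 1, "trial": range(n),
        "set_size": set_sizes, "stimulus": [f"b01_s{i % 2}" for i in range(n)],
        "iteration": [i // 2 + 1 for i in range(n)],
        "action": [0 if r else 1 for r in rewards], "correct_action": 0,
        "reward": list(rewards),
        "rt_ms": rts if np.ndim(rts) else [rts] * n, "valid": True})
    return SubjectDataset(subject_id=subject_id, trials=df, group=group,
                          age=age, moca=moca)


def test_summary_accuracy_rt_ies():
    s = summarize_subject(_dataset(rewards=(1, 1, 1, 1, 0, 0), rts=600.0))
    assert s.accuracy == pytest.approx(4 / 6)
    assert s.mean_rt == pytest.approx(600.0)
    assert s.ies == pytest.approx(900.0)   # 600 / (2/3)
    s2 = summarize_subject(_dataset(rewards=(1, 1, 1, 0), rts=600.0))
    assert s2.ies == pytest.approx(800.0)  # 600 / 0.75


def test_summary_per_set_size_hand_counts():
    ds = _dataset(rewards=(1, 0, 1, 1, 0, 0, 1, 1),
                  set_sizes=[2, 2, 2, 2, 3, 3, 3, 3])
    s = summarize_subject(ds)
    assert s.accuracy_by_ns == {2: pytest.approx(3 / 4), 3: pytest.approx(2 / 4)}


def test_exclusion_boundary():
    subs = [summarize_subject(_dataset(subject_id=f"s{i}", rewards=r))
            for i, r in enumerate([(1,) * 32 + (0,) * 68,   # 0.32: excluded
                                   (1,) * 33 + (0,) * 67,   # 0.33: kept (strict)
                                   (1,) * 34 + (0,) * 66])]  # 0.34: kept
    kept, excluded = apply_exclusion(subs)
    assert [s.subject_id for s in excluded] == ["s0"]
    assert [s.subject_id for s in kept] == ["s1", "s2"]
    assert "accuracy 0.320" in excluded[0].exclusion_reason


def test_compare_groups_identical_samples():
    x = np.array([1.0, 1.0, 2.0, 3.0, 5.0, 8.0, 9.0, 9.0])
    rep = compare_groups({"a": x, "b": x.copy()})
    assert rep.p_raw == pytest.approx(1.0)
    assert rep.effect_size == 0.0


def test_compare_groups_complete_separation():
    rep = compare_groups({"lo": np.arange(1, 21), "hi": np.arange(101, 121)})
    assert rep.p_raw < 1e-3
    assert rep.effect_size < 0  # first group minus second


def test_compare_groups_branching_and_bonferroni():
    rng = np.random.default_rng(0)
    normal = {"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30)}
    rep = compare_groups(normal, family_size=4)
    assert rep.test == "welch-t"
    assert rep.p_adjusted == pytest.approx(min(1.0, rep.p_raw * 4))
    skewed = {"a": rng.exponential(1, 40) ** 3, "b": rng.exponential(1, 40) ** 3}
    assert compare_groups(skewed).test == "mann-whitney-u"
    with pytest.raises(ValueError):
        compare_groups({"a": [1, 2], "b": [1, 2, 3]})


def test_compare_groups_power_at_d08():
    """True d = 0.8, n = 30/group: significant in at least 80% of replicates."""
    rng = np.random.default_rng(12)
    hits = 0
    for _ in range(200):
        rep = compare_groups({"a": rng.normal(0.8, 1, 30),
                              "b": rng.normal(0.0, 1, 30)})
        hits += rep.p_raw < 0.05
    assert hits >= 160


def test_age_trend_cases():
    ages = np.arange(20, 60, dtype=float)
    out = age_trend(ages.copy(), ages, "self")
    assert out["spearman"].statistic == pytest.approx(1.0)
    assert out["regression"].effect_size == pytest.approx(1.0)
    rng = np.random.default_rng(3)
    noise = age_trend(rng.normal(size=40), ages, "null")
    assert abs(noise["spearman"].statistic) < 0.3
    assert noise["spearman"].p_raw > 0.05
    down = age_trend(-ages + rng.normal(0, 1e-9, 40), ages, "down")
    assert down["spearman"].statistic == pytest.approx(-1.0)


def test_parameter_correlation_matrix():
    rng = np.random.default_rng(1)
    x = rng.normal(size=1000)
    tbl = pd.DataFrame({"alpha": x, "rho": x * 2 + 1,          # perfectly coupled
                        "epsilon": rng.normal(size=1000),
                        "phi": rng.normal(size=1000)})
    out = parameter_correlation_matrix(tbl)
    coef = out["coefficients"]
    assert coef.loc["alpha", "rho"] == pytest.approx(1.0)
    assert abs(coef.loc["epsilon", "phi"]) < 0.1
    assert np.allclose(coef.values, coef.values.T)
    assert (np.diag(coef.values) == 1).all()
    assert (np.diag(out["p_values"].values) == 0).all()
    with pytest.raises(ValueError):
        parameter_correlation_matrix(tbl.iloc[:3])


def _classifier_frame(n=96, jump_at=40, seed=0):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(25, 60, n)
    rows = {"subject_id": [f"s{i}" for i in range(n)], "age": ages}
    for ns in (2, 3, 4, 5):
        rows[f"rt{ns}"] = 500 + 400 * (ages > jump_at) + rng.normal(0, 5, n)
        rows[f"correct{ns}"] = rng.uniform(0.5, 1.0, n)
    return pd.DataFrame(rows)


def test_logistic_classifier_finds_discontinuity():
    out = logistic_age_classifier(_classifier_frame(), seed=0)
    assert out["best_cutoff"] == 40
    row = out["table"].set_index("cutoff").loc[40]
    assert row["test_accuracy"] == 1.0


def test_logistic_classifier_null_near_majority_rate():
    rng = np.random.default_rng(5)
    df = _classifier_frame(seed=5)
    for ns in (2, 3, 4, 5):   # sever the age link
        df[f"rt{ns}"] = rng.normal(800, 50, len(df))
    out = logistic_age_classifier(df, seed=1)
    maj = max((df["age"] > 40).mean(), 1 - (df["age"] > 40).mean())
    acc40 = out["table"].set_index("cutoff").loc[40, "test_accuracy"]
    assert acc40 < maj + 0.25


def test_logistic_classifier_deterministic_and_skips():
    df = _classifier_frame(n=40)
    a = logistic_age_classifier(df, cutoffs=range(30, 60), seed=3)
    b = logistic_age_classifier(df, cutoffs=range(30, 60), seed=3)
    pd.testing.assert_frame_equal(a["table"], b["table"])
    assert a["skipped_cutoffs"]  # extreme cutoffs leave a class too small


def test_anova_by_factor():
    rng = np.random.default_rng(2)
    vals = np.r_[rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(2, 1, 30)]
    labels = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
    out = anova_by_factor(vals, labels)
    assert out["anova_p"] < 1e-3
    row = out["tukey"].set_index(["group1", "group2"]).loc[("a", "b")]
    diff = vals[30:60].mean() - vals[:30].mean()
    assert float(row["meandiff"]) == pytest.approx(diff, abs=1e-4)
    flat = anova_by_factor([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
    assert flat["zero_variance"] and flat["anova_F"] == 0.0
    with pytest.raises(ValueError):
        anova_by_factor([1, 2, 3], ["a", "a", "b"])


def test_rt_regression_recovers_known_coefficients():
    rng = np.random.default_rng(4)
    phis = rng.uniform(0, 1, 200)
    rhos = rng.uniform(0, 1, 200)
    rt = 650 + 700 * phis + 150 * rhos + rng.normal(0, 5, 200)
    out = rt_parameter_regression(rt, phis, rhos)
    assert abs(out["coef"]["phi"] - 700) <= 2 * out["se"]["phi"]
    assert abs(out["coef"]["prior"] - 150) <= 2 * out["se"]["prior"]
    assert out["r_squared"] > 0.99


def test_speed_accuracy_analysis_structure():
    g1 = [_dataset(f"a{i}", rewards=(1, 1, 0, 1, 0, 1),
                   rts=[500, 510, 700, 505, 690, 495], group="g1")
          for i in range(4)]
    g2 = [_dataset(f"b{i}", rewards=(1, 0, 0, 1, 1, 1),
                   rts=[600, 800, 805, 610, 620, 590], group="g2")
          for i in range(4)]
    out = speed_accuracy_analysis(g1 + g2)
    for g in ("g1", "g2"):
        assert out[g]["mean_rt_error"] > out[g]["mean_rt_correct"]


def test_summaries_frame_has_classifier_features():
    ds = _dataset(rewards=(1, 0, 1, 1, 0, 0, 1, 1),
                  set_sizes=[2, 2, 2, 2, 3, 3, 3, 3])
    frame = summaries_frame([summarize_subject(ds)])
    for col in ("rt2", "rt3", "correct2", "correct3", "ies", "accuracy"):
        assert col in frame.columns
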