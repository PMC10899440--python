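"""Behavioral summaries and the group-comparison statistical battery.

Covers: per-subject accuracy/RT summaries and the inverse efficiency score
(IES = mean RT / proportion correct), chance-level exclusion, normality-gated
two-group comparisons (Shapiro-Wilk -> Mann-Whitney U or Welch's t) with
Cohen's d and Bonferroni adjustment, age trends (Spearman and linear
regression, reported together), parameter correlation matrices, a logistic
age-group classifier over candidate cut-offs, one-way ANOVAs with Tukey HSD,
and the speed-accuracy analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .curves import LearningCurveFit, learning_initiation
from .task import SubjectDataset

EXCLUSION_ACCURACY = 0.33  # strictly below => chance-level responding
SHAPIRO_ALPHA = 0.05       # normality gate for the two-sample branch


@dataclass
class SubjectSummary:
    """Per-subject behavioral metrics over valid learning-block trials."""

    subject_id: str
    age: Optional[float]
    group: Optional[str]
    moca: Optional[int]
    accuracy: float
    accuracy_by_ns: dict
    mean_rt: Optional[float]
    rt_by_ns: dict
    ies: Optional[float]
    excluded: bool = False
    exclusion_reason: Optional[str] = None


def summarize_subject(dataset: SubjectDataset) -> SubjectSummary:
    """Accuracy, RT and IES; means over valid learning-block trials only."""
    df = dataset.learning_trials
    if df.empty:
        raise ValueError(f"subject {dataset.subject_id}: no valid learning trials")
    acc = float(df["reward"].mean())
    acc_ns = {int(ns): float(g["reward"].mean()) for ns, g in df.groupby("set_size")}
    has_rt = df["rt_ms"].notna().any()
    mean_rt = float(df["rt_ms"].mean()) if has_rt else None
    rt_ns = ({int(ns): float(g["rt_ms"].mean()) for ns, g in df.groupby("set_size")}
             if has_rt else {})
    ies = (mean_rt / acc) if (has_rt and acc > 0) else None
    return SubjectSummary(subject_id=dataset.subject_id, age=dataset.age,
                          group=dataset.group, moca=dataset.moca,
                          accuracy=acc, accuracy_by_ns=acc_ns,
                          mean_rt=mean_rt, rt_by_ns=rt_ns, ies=ies)


def summaries_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"subject_id": s.subject_id, "age": s.age, "group": s.group,
               "moca": s.moca, "accuracy": s.accuracy, "mean_rt": s.mean_rt,
               "ies": s.ies, "excluded": s.excluded,
               "exclusion_reason": s.exclusion_reason}
        for ns in (2, 3, 4, 5):
            row[f"correct{ns}"] = s.accuracy_by_ns.get(ns, np.nan)
            row[f"rt{ns}"] = s.rt_by_ns.get(ns, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def apply_exclusion(summaries: Sequence[SubjectSummary],
                    threshold: float = EXCLUSION_ACCURACY):
    """Exclude subjects whose overall accuracy is strictly below threshold."""
    kept, excluded = [], []
    for s in summaries:
        if s.accuracy < threshold:
            s.excluded = True
            s.exclusion_reason = f"accuracy {s.accuracy:.3f} < {threshold}"
            excluded.append(s)
        else:
            kept.append(s)
    return kept, excluded


@dataclass
class StatReport:
    """One statistical test with its adjusted p and effect size."""

    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    family_size: int
    effect_size: Optional[float]
    effect_size_name: Optional[str]
    group_ns: dict
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic,
                "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
                "family_size": self.family_size, "effect_size": self.effect_size,
                "effect_size_name": self.effect_size_name,
                "group_ns": self.group_ns, **self.extra}


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardised mean difference (pooled SD, first group minus second)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def bonferroni(p: float, family_size: int) -> float:
    return float(min(1.0, p * family_size))


def compare_groups(values_by_group: dict, family_size: int = 1) -> StatReport:
    """Normality-gated two-sample comparison.

    Shapiro-Wilk on each group; if either deviates (p < 0.05) the comparison
    is a Mann-Whitney U test, otherwise Welch's t.  Cohen's d is always
    reported; the Bonferroni adjustment uses the declared family size.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups required")
    (ga, a), (gb, b) = values_by_group.items()
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    shapiro = {}
    non_normal = False
    for name, x in ((ga, a), (gb, b)):
        if np.ptp(x) == 0:
            shapiro[name] = 0.0   # a constant sample is certainly non-normal
            non_normal = True
        else:
            p = float(sps.shapiro(x).pvalue)
            shapiro[name] = p
            non_normal = non_normal or p < SHAPIRO_ALPHA
    if non_normal:
        if np.array_equal(np.sort(a), np.sort(b)):
            stat, p_raw = float(len(a) * len(b) / 2), 1.0
        else:
            stat, p_raw = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney-u"
    else:
        stat, p_raw = sps.ttest_ind(a, b, equal_var=False)
        test = "welch-t"
    return StatReport(test=test, statistic=float(stat), p_raw=float(p_raw),
                      p_adjusted=bonferroni(float(p_raw), family_size),
                      family_size=family_size, effect_size=cohens_d(a, b),
                      effect_size_name="cohens_d",
                      group_ns={ga: len(a), gb: len(b)},
                      extra={"shapiro_p": shapiro, "groups": [ga, gb]})


def age_trend(values: Sequence[float], ages: Sequence[float],
              subset_label: str = "") -> dict:
    """Spearman correlation and linear regression of a metric on age.

    Both are reported together: a monotone association can be significant
    while the linear model is not (and vice versa).
    """
    values = np.asarray(values, float)
    ages = np.asarray(ages, float)
    if len(values) != len(ages) or len(values) < 4:
        raise ValueError("need >= 4 paired observations")
    rho, p_rho = sps.spearmanr(ages, values)
    lr = sps.linregress(ages, values)
    return {
        "subset": subset_label,
        "n": int(len(values)),
        "spearman": StatReport(test="spearman", statistic=float(rho),
                               p_raw=float(p_rho), p_adjusted=float(p_rho),
                               family_size=1, effect_size=float(rho),
                               effect_size_name="spearman_rho",
                               group_ns={subset_label or "all": len(values)}),
        "regression": StatReport(test="linear-regression",
                                 statistic=float(lr.slope / lr.stderr) if lr.stderr > 0 else np.inf,
                                 p_raw=float(lr.pvalue), p_adjusted=float(lr.pvalue),
                                 family_size=1, effect_size=float(lr.rvalue ** 2),
                                 effect_size_name="r_squared",
                                 group_ns={subset_label or "all": len(values)},
                                 extra={"slope": float(lr.slope),
                                        "intercept": float(lr.intercept)}),
    }


def parameter_correlation_matrix(params_table: pd.DataFrame,
                                 columns: Sequence[str] = ("alpha", "rho", "epsilon", "phi")
                                 ) -> dict:
    """Pairwise Pearson coefficient and p-value matrices over fitted parameters.

    Both matrices are reported (published parameter tables of this kind mix
    coefficients and significance stars); the diagonal is 1 / 0.
    """
    if len(params_table) < 4:
        raise ValueError("need >= 4 fits")
    cols = list(columns)
    k = len(cols)
    coef = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = params_table[cols[i]].to_numpy(float)
            y = params_table[cols[j]].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                res = sps.pearsonr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            coef[i, j] = coef[j, i] = r
            pval[i, j] = pval[j, i] = p
    return {"coefficients": pd.DataFrame(coef, index=cols, columns=cols),
            "p_values": pd.DataFrame(pval, index=cols, columns=cols)}


def logistic_age_classifier(summaries: pd.DataFrame,
                            cutoffs: Sequence[int] = tuple(range(35, 45)),
                            seed: int = 0, test_size: float = 0.25) -> dict:
    """Predict 'aged' (age > cutoff) from per-set-size RT and accuracy.

    Features are rt2..rt5 and correct2..correct5.  For each candidate cutoff
    the data are split 75/25 stratified (seeded), a logistic regression is fit
    on the training part, and test accuracy is reported; the best cutoff is
    the accuracy argmax.  Cutoffs yielding a class too small to stratify are
    skipped and flagged.
    """
    feats = [f"rt{ns}" for ns in (2, 3, 4, 5)] + [f"correct{ns}" for ns in (2, 3, 4, 5)]
    missing = [f for f in feats if f not in summaries.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = summaries[feats].to_numpy(float)
    ages = summaries["age"].to_numpy(float)
    rows = []
    skipped = []
    for cutoff in cutoffs:
        y = (ages > cutoff).astype(int)
        if min(np.bincount(y, minlength=2)) < 4:
            skipped.append(int(cutoff))
            continue
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=test_size,
                                              random_state=seed, stratify=y)
        clf = make_pipeline(StandardScaler(),
                            LogisticRegression(max_iter=2000))
        clf.fit(Xtr, ytr)
        rows.append({"cutoff": int(cutoff),
                     "test_accuracy": float(clf.score(Xte, yte)),
                     "n_aged": int(y.sum()), "n_young": int(len(y) - y.sum())})
    table = pd.DataFrame(rows)
    best = None
    if not table.empty:
        best = int(table.loc[table["test_accuracy"].idxmax(), "cutoff"])
    return {"table": table, "best_cutoff": best, "skipped_cutoffs": skipped}


def anova_by_factor(values: Sequence[float], factor_labels: Sequence[str]) -> dict:
    """One-way ANOVA with Tukey HSD pairwise differences."""
    values = np.asarray(values, float)
    labels = np.asarray(factor_labels)
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("need >= 2 factor levels")
    samples = []
    for lev in levels:
        x = values[labels == lev]
        if len(x) < 2:
            raise ValueError(f"level {lev!r} has n < 2")
        samples.append(x)
    if all(np.ptp(x) == 0 for x in samples) and len({x[0] for x in samples}) == 1:
        return {"anova_F": 0.0, "anova_p": 1.0, "tukey": None,
                "zero_variance": True}
    F, p = sps.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, labels)
    tk = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return {"anova_F": float(F), "anova_p": float(p), "tukey": tk,
            "zero_variance": False}


def rt_parameter_regression(mean_rts: Sequence[float], phis: Sequence[float],
                            rhos: Sequence[float]) -> dict:
    """OLS of subject mean RT on WM decay and WM prior (RT ~ phi + prior)."""
    import statsmodels.api as sm
    Xd = pd.DataFrame({"phi": np.asarray(phis, float),
                       "prior": np.asarray(rhos, float)})
    model = sm.OLS(np.asarray(mean_rts, float), sm.add_constant(Xd)).fit()
    return {
        "r_squared": float(model.rsquared),
        "coef": {k: float(v) for k, v in model.params.items()},
        "se": {k: float(v) for k, v in model.bse.items()},
        "p": {k: float(v) for k, v in model.pvalues.items()},
        "n": int(model.nobs),
    }


def speed_accuracy_analysis(datasets: Sequence[SubjectDataset],
                            growth_fits: Optional[dict] = None,
                            initiation_fraction: float = 0.1) -> dict:
    """Per-group correct vs. error RT and the accuracy-on-RT regression.

    ``growth_fits`` maps group name -> :class:`LearningCurveFit`; when given,
    the correct/error RT contrast is also reported restricted to trials at or
    after the group's learning-initiation iteration.
    """
    by_group: dict[str, dict] = {}
    groups = sorted({d.group for d in datasets if d.group is not None})
    for g in groups:
        members = [d for d in datasets if d.group == g]
        trials = pd.concat([d.learning_trials for d in members], ignore_index=True)
        trials = trials[trials["rt_ms"].notna()]
        if trials.empty:
            continue
        correct = trials[trials["reward"] == 1]["rt_ms"]
        error = trials[trials["reward"] == 0]["rt_ms"]
        entry = {
            "n_trials": int(len(trials)),
            "mean_rt_correct": float(correct.mean()) if len(correct) else None,
            "mean_rt_error": float(error.mean()) if len(error) else None,
        }
        init_t = None
        if growth_fits and g in growth_fits:
            init_t = learning_initiation(growth_fits[g], fraction=initiation_fraction)
        entry["initiation_iteration"] = init_t
        if init_t is not None:
            post = trials[trials["iteration"] >= init_t]
            pc = post[post["reward"] == 1]["rt_ms"]
            pe = post[post["reward"] == 0]["rt_ms"]
            entry["post_initiation"] = {
                "n_trials": int(len(post)),
                "mean_rt_correct": float(pc.mean()) if len(pc) else None,
                "mean_rt_error": float(pe.mean()) if len(pe) else None,
            }
        # speed-accuracy tradeoff across subjects within the group
        accs = [d.learning_trials["reward"].mean() for d in members]
        rts = [d.learning_trials["rt_ms"].mean() for d in members]
        if len(members) >= 4 and np.ptp(rts) > 0:
            lr = sps.linregress(rts, accs)
            entry["accuracy_on_rt"] = {"r_squared": float(lr.rvalue ** 2),
                                       "p": float(lr.pvalue),
                                       "slope": float(lr.slope)}
        by_group[g] = entry
    return by_group
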