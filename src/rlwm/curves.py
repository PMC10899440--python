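"""Iteration-aligned learning curves and logistic growth fits.

A learning curve is the mean proportion of correct responses at each
presentation index (the n-th time any stimulus has been seen), pooled across
stimuli and subjects, optionally split by set size.  The curve is summarised
by the three-parameter logistic growth model

    P(t) = A / (1 + B * exp(-k * t))

with asymptote ``A``, scaling ``B`` and growth rate (inverse time constant)
``k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .task import SubjectDataset

GROWTH_BOUNDS = ((1e-6, 1.0), (1e-6, 1e3), (1e-6, 10.0))  # A, B, k


def logistic_growth(t, A, B, k):
    t = np.asarray(t, dtype=float)
    return A / (1.0 + B * np.exp(-k * t))


def compute_learning_curves(datasets: Iterable[SubjectDataset] | pd.DataFrame,
                            by_set_size: bool = True) -> pd.DataFrame:
    """Mean accuracy per presentation index, balanced across cells.

    Pools valid learning-block trials from all subjects and truncates at the
    minimum per-stimulus presentation count so every iteration cell draws on
    the same stimuli.  Returns columns ``set_size`` (int or "all"),
    ``iteration``, ``mean_correct``, ``n``.
    """
    if isinstance(datasets, pd.DataFrame):
        pooled = datasets
        pooled = pooled[(pooled["block"] > 0) & pooled["valid"].astype(bool)]
    else:
        frames = [ds.learning_trials for ds in datasets]
        if not frames:
            raise ValueError("no datasets given")
        pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        raise ValueError("no valid learning trials")
    t_max = int(pooled.groupby(["subject_id", "block", "stimulus"])["iteration"]
                .max().min())
    pooled = pooled[pooled["iteration"] <= t_max]
    key = ["set_size", "iteration"] if by_set_size else ["iteration"]
    g = pooled.groupby(key)["reward"].agg(["mean", "size"]).reset_index()
    if not by_set_size:
        g.insert(0, "set_size", "all")
    g = g.rename(columns={"mean": "mean_correct", "size": "n"})
    return g


@dataclass
class LearningCurveFit:
    """Fitted logistic growth parameters over a curve's iteration domain."""

    A: float
    B: float
    k: float
    rss: float
    t_min: int
    t_max: int
    converged: bool = True
    degenerate: bool = False

    def predict(self, t) -> np.ndarray:
        return logistic_growth(t, self.A, self.B, self.k)

    def to_dict(self) -> dict:
        return {"A": self.A, "B": self.B, "k": self.k, "rss": self.rss,
                "converged": self.converged, "degenerate": self.degenerate}


class LogisticGrowthCurve(BaseEstimator, RegressorMixin):
    """Bounded least-squares fit of the logistic growth model.

    Deterministic: initialisation is a fixed rule (``A0 = max(y)``,
    ``k0 = 0.5``, ``B0`` solved from the first point).  Curves with no
    measurable growth are flagged ``degenerate_`` and returned with ``B`` and
    ``k`` at their lower bounds rather than mis-fit.
    """

    def __init__(self, flat_tol: float = 1e-3, max_nfev: int = 2000):
        self.flat_tol = flat_tol
        self.max_nfev = max_nfev

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).ravel()
        p = np.asarray(y, dtype=float).ravel()
        if len(t) != len(p) or len(t) < 4:
            raise ValueError("need >= 4 (iteration, accuracy) points")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        (a_lo, a_hi), (b_lo, b_hi), (k_lo, k_hi) = GROWTH_BOUNDS
        self.t_min_, self.t_max_ = int(t.min()), int(t.max())
        if np.ptp(p) < self.flat_tol:
            # no growth: asymptote at the mean, scaling/rate pinned at bounds
            self.A_, self.B_, self.k_ = float(np.clip(p.mean(), a_lo, a_hi)), b_lo, k_lo
            self.rss_ = float(np.sum((p - self.predict(t)) ** 2))
            self.converged_ = True
            self.degenerate_ = True
            return self
        A0 = float(np.clip(p.max(), 0.05, 1.0))
        k0 = 0.5
        p1 = float(np.clip(p[np.argmin(t)], 1e-3, None))
        B0 = float(np.clip((A0 / p1 - 1.0) * np.exp(k0 * t.min()), b_lo, b_hi))
        try:
            popt, _ = optimize.curve_fit(
                logistic_growth, t, p, p0=[A0, B0, k0],
                bounds=([a_lo, b_lo, k_lo], [a_hi, b_hi, k_hi]),
                max_nfev=self.max_nfev)
            self.converged_ = True
        except RuntimeError:
            popt = [A0, B0, k0]
            self.converged_ = False
        self.A_, self.B_, self.k_ = map(float, popt)
        self.rss_ = float(np.sum((p - self.predict(t)) ** 2))
        self.degenerate_ = False
        return self

    def predict(self, X) -> np.ndarray:
        return logistic_growth(np.asarray(X, dtype=float).ravel(),
                               self.A_, self.B_, self.k_)

    def result_(self) -> LearningCurveFit:
        return LearningCurveFit(A=self.A_, B=self.B_, k=self.k_, rss=self.rss_,
                                t_min=self.t_min_, t_max=self.t_max_,
                                converged=self.converged_,
                                degenerate=self.degenerate_)


def fit_logistic_growth(curve: pd.DataFrame | Sequence,
                        values: Optional[Sequence] = None) -> LearningCurveFit:
    """Fit the growth model to a curve (DataFrame or ``(t, p)`` arrays)."""
    if isinstance(curve, pd.DataFrame):
        t = curve["iteration"].to_numpy(dtype=float)
        p = curve["mean_correct"].to_numpy(dtype=float)
    else:
        t = np.asarray(curve, dtype=float)
        p = np.asarray(values, dtype=float)
    est = LogisticGrowthCurve().fit(t, p)
    return est.result_()


def learning_initiation(fit: LearningCurveFit, fraction: float = 0.1,
                        rule: str = "baseline", t_max: Optional[int] = None) -> Optional[int]:
    """First iteration at which the fitted curve clears a growth threshold.

    ``rule="baseline"`` (default): smallest integer t with
    ``(P(t) - P(0)) / (A - P(0)) >= fraction`` -- the rise above the curve's
    pre-learning baseline ``P(0)``, normalised by the total attainable rise.
    ``rule="literal"``: smallest t with ``P(t) >= fraction * A``; note this is
    typically satisfied at t = 1.  Returns ``None`` if the threshold is never
    reached within the fit domain or the fit is degenerate.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    t_hi = t_max if t_max is not None else fit.t_max
    ts = np.arange(1, t_hi + 1)
    pt = fit.predict(ts)
    if rule == "literal":
        hits = np.flatnonzero(pt >= fraction * fit.A)
    elif rule == "baseline":
        p0 = float(fit.predict(0))
        if fit.A <= p0 or fit.degenerate:
            return None
        hits = np.flatnonzero((pt - p0) / (fit.A - p0) >= fraction)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return int(ts[hits[0]]) if hits.size else None


def compare_growth_parameters(fits: pd.DataFrame, group_col: str = "group") -> dict:
    """One-way ANOVA plus Tukey HSD on the growth rate ``k`` and asymptote ``A``.

    ``fits`` must carry one row per subject with columns ``k``, ``A`` and the
    group label.  Requires >= 2 groups with >= 2 fits each.
    """
    groups = fits[group_col].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        sub = fits[fits[group_col] == g]
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 fits")
    report = {}
    for param in ("k", "A"):
        samples = [fits.loc[fits[group_col] == g, param].to_numpy() for g in groups]
        F, p = stats.f_oneway(*samples)
        tukey = pairwise_tukeyhsd(fits[param].to_numpy(),
                                  fits[group_col].to_numpy())
        tk = pd.DataFrame(tukey.summary().data[1:],
                          columns=tukey.summary().data[0])
        report[param] = {"anova_F": float(F), "anova_p": float(p),
                         "tukey": tk}
    return report


def ratio_identity(mean_alpha: dict, mean_phi: dict, tau: dict, rt: dict,
                   g1: str, g2: str) -> dict:
    """Compare the learning/decay-rate ratio with the time-constant x RT ratio.

    lhs = (alpha_g1 / alpha_g2) / (phi_g1 / phi_g2);
    rhs = (tau_g1 / tau_g2) * (RT_g1 / RT_g2).  Reported with the relative
    gap |lhs - rhs| / rhs; equality is an empirical observation, not asserted.
    """
    for d in (mean_alpha, mean_phi, tau, rt):
        for g in (g1, g2):
            if d[g] <= 0:
                raise ValueError(f"non-positive value for group {g!r}")
    lhs = (mean_alpha[g1] / mean_alpha[g2]) / (mean_phi[g1] / mean_phi[g2])
    rhs = (tau[g1] / tau[g2]) * (rt[g1] / rt[g2])
    return {"lhs": float(lhs), "rhs": float(rhs),
            "relative_gap": float(abs(lhs - rhs) / rhs)}
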