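"""ROC/AUC, operating points, bootstrap CIs, the DeLong test and
Table-1-style baseline group comparisons.

Scores are oriented so that larger means higher mortality risk; the
positive class is death.  The AUC is the empirical (trapezoid) area,
identical to the mid-rank Mann–Whitney statistic; AUCs below 0.5 are
reported as-is.  The DeLong test compares two correlated ROC curves via
placement-value (structural-component) covariances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "RocCurve",
    "OperatingPoint",
    "DeLongResult",
    "roc_and_auc",
    "best_operating_point",
    "bootstrap_ci",
    "delong_test",
    "delong_auc_variance",
    "chi_square_test",
    "baseline_comparison",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden_j: float


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p_value: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    return labels


def roc_and_auc(scores, labels) -> RocCurve:
    """Empirical ROC over all thresholds; AUC by trapezoid (= mid-rank
    Mann–Whitney)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=float(roc_auc_score(labels, scores))
    )


def best_operating_point(scores, labels) -> OperatingPoint:
    """Threshold maximising Youden's J (ties broken toward higher
    specificity), with sens/spec/PPV/NPV from the confusion counts.

    A subject is called positive when ``score >= threshold``.  PPV/NPV are
    at the sample prevalence; an empty predicted class yields NaN for the
    corresponding predictive value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    best = None
    for t in np.unique(scores):
        called = scores >= t
        tp = int((called & pos).sum())
        fp = int((called & ~pos).sum())
        sens = tp / n_pos
        spec = (n_neg - fp) / n_neg
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2]
        ):
            best = (j, sens, spec, t, tp, fp)
    j, sens, spec, t, tp, fp = best
    fn = n_pos - tp
    tn = n_neg - fp
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return OperatingPoint(
        threshold=float(t),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        youden_j=j,
    )


def bootstrap_ci(
    metric,
    scores,
    labels,
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified nonparametric bootstrap percentile interval for
    ``metric(scores, labels)``.  Resampling within each class keeps every
    resample two-class; a degenerate draw (possible only for degenerate
    inputs) is redrawn."""
    if reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    vals = np.empty(reps)
    redraws = 0
    for r in range(reps):
        while True:
            take = np.concatenate(
                [
                    rng.choice(idx_pos, size=len(idx_pos), replace=True),
                    rng.choice(idx_neg, size=len(idx_neg), replace=True),
                ]
            )
            if len(np.unique(labels[take])) == 2:
                break
            redraws += 1
        vals[r] = metric(scores[take], labels[take])
    if redraws:
        warnings.warn(f"{redraws} degenerate bootstrap resamples redrawn")
    alpha = (1 - level) / 2
    return (
        float(np.quantile(vals, alpha)),
        float(np.quantile(vals, 1 - alpha)),
    )


def _placements(scores: np.ndarray, labels: np.ndarray):
    """Mid-rank placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # mid-ranks
    ranks_pos = ranks[:m]
    ranks_neg = ranks[m:]
    # rank within own group, mid-rank as well
    v10 = (ranks_pos - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_neg - stats.rankdata(neg)) / m
    return v10, v01


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance for a single score vector."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong comparison of two ROC curves on the same subjects.

    Identical score vectors give difference 0 and p = 1 (no division
    error).  The z statistic is invariant to strictly monotone transforms
    of either score vector (only mid-ranks enter).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must cover the same subjects")
    labels = _check_binary(labels)
    if len(labels) != len(scores_a):
        raise ValueError("labels and scores differ in length")

    v10a, v01a = _placements(scores_a, labels)
    v10b, v01b = _placements(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    var_diff = max(var_diff, 0.0)
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0
        p = 1.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(
        auc_a=auc_a,
        auc_b=auc_b,
        difference=diff,
        variance=var_diff,
        z=float(z),
        p_value=p,
    )


def chi_square_test(table, correction: bool = False):
    """Pearson chi-square on a contingency table (no continuity
    correction by default).  Returns (statistic, p, dof, expected)."""
    res = stats.chi2_contingency(np.asarray(table), correction=correction)
    return res.statistic, res.pvalue, res.dof, res.expected_freq


def _is_binary(x: pd.Series) -> bool:
    vals = set(x.dropna().unique())
    return len(vals) <= 2 and vals <= {0, 1, 0.0, 1.0, True, False}


def baseline_comparison(
    df: pd.DataFrame,
    group_col: str = "outcome",
    variables: list[str] | None = None,
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group comparison in the style of a baseline table.

    Continuous variables: mean ± SD with Student's t when a Shapiro
    normality check passes in both groups, else median (IQR) with the
    Mann–Whitney U.  Binary variables: counts (%) with Pearson chi-square
    (uncorrected), Fisher's exact substituted when any expected cell < 5.
    Zero-variance variables are reported without a test.
    """
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g0 = df[df[group_col] == groups[0]]
    g1 = df[df[group_col] == groups[1]]
    if variables is None:
        variables = [c for c in df.columns if c != group_col]

    rows = []
    for var in variables:
        x0 = g0[var].dropna()
        x1 = g1[var].dropna()
        all_x = df[var].dropna()
        if all_x.nunique() <= 1:
            rows.append(
                dict(variable=var, kind="constant", test="none",
                     summary_g0=f"{all_x.iloc[0] if len(all_x) else float('nan')}",
                     summary_g1="", statistic=np.nan, p_value=np.nan)
            )
            continue
        if _is_binary(df[var]):
            table = np.array(
                [
                    [(x0 == 1).sum(), (x0 != 1).sum()],
                    [(x1 == 1).sum(), (x1 != 1).sum()],
                ]
            )
            expected = stats.chi2_contingency(table, correction=False).expected_freq
            if (expected < 5).any():
                odds, p = stats.fisher_exact(table)
                test, stat = "fisher", odds
            else:
                stat, p, _, _ = chi_square_test(table, correction=False)
                test = "chi2"
            s0 = f"{table[0, 0]} ({100 * table[0, 0] / len(x0):.1f}%)"
            s1 = f"{table[1, 0]} ({100 * table[1, 0] / len(x1):.1f}%)"
        else:
            normal = (
                len(x0) >= 3
                and len(x1) >= 3
                and x0.nunique() > 1
                and x1.nunique() > 1
                and stats.shapiro(x0).pvalue > alpha_normality
                and stats.shapiro(x1).pvalue > alpha_normality
            )
            if normal:
                stat, p = stats.ttest_ind(x0, x1)
                test = "t"
                s0 = f"{x0.mean():.2f} ± {x0.std():.2f}"
                s1 = f"{x1.mean():.2f} ± {x1.std():.2f}"
            else:
                stat, p = stats.mannwhitneyu(x0, x1, alternative="two-sided")
                test = "mannwhitney"
                s0 = (
                    f"{x0.median():.2f} "
                    f"({x0.quantile(0.25):.2f}, {x0.quantile(0.75):.2f})"
                )
                s1 = (
                    f"{x1.median():.2f} "
                    f"({x1.quantile(0.25):.2f}, {x1.quantile(0.75):.2f})"
                )
        rows.append(
            dict(
                variable=var,
                kind="binary" if _is_binary(df[var]) else "continuous",
                test=test,
                summary_g0=s0,
                summary_g1=s1,
                statistic=float(stat),
                p_value=float(p),
            )
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < 0.05
    return out
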