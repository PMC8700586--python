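"""Group-level statistical battery.

Paired t-tests with Bonferroni adjustment, one-way ANOVA with Tukey's HSD
post hoc test, and logistic-regression ROC analysis of labelled voxels. The
statistics are computed from their defining formulas; only the reference
distributions (Student t, F, studentized range) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

#: Default Bonferroni family: the eight ROI summary variables tested per
#: region. Whether the family should also span regions is a study choice;
#: pass ``family_size`` explicitly to change it.
DEFAULT_FAMILY_SIZE = 8


class DegenerateDataError(ValueError):
    """Statistic undefined on this input (zero variance)."""


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p-value and the
    optional multiplicity-adjusted p-value."""

    statistic: float
    df: Tuple[float, ...]
    p_value: float
    p_adjusted: Optional[float] = None
    comparison: str = ""


@dataclass(frozen=True)
class ROCResult:
    """ROC curve and area for one two-class voxel contrast.

    ``auc`` is the trapezoidal area under (fpr, tpr); with a univariate
    logistic score it equals the Mann-Whitney probability that a random
    positive outranks a random negative (ties count one half).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_label: str = "pos"
    used_fallback: bool = False


def paired_ttest(x: Sequence[float], y: Sequence[float], comparison: str = "") -> TestResult:
    """Two-sided paired t-test on differences x - y.

    t = mean(d) / (sd(d)/sqrt(n)) with the unbiased sd and n-1 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("all pairwise differences are equal; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(statistic=float(t), df=(n - 1,), p_value=float(p), comparison=comparison)


def bonferroni(p_values: Sequence[float], family_size: Optional[int] = None) -> np.ndarray:
    """p_adj = min(1, m * p). ``family_size`` defaults to len(p_values) but
    may be larger when the reported p-values are a subset of the family."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if family_size is None else family_size
    if m < p.size:
        raise ValueError("family_size must be >= number of p-values")
    return np.minimum(1.0, m * p)


def anova_tukey(groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None):
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Returns ``(omnibus, pairwise)``: the F test (df = (k-1, N-k)) and a list
    of Tukey results, one per group pair, with q statistics referred to the
    studentized range distribution. Unbalanced groups use the Tukey-Kramer
    form q = |mean_i - mean_j| / sqrt(MS_w/2 * (1/n_i + 1/n_j)).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    ns = np.array([a.size for a in arrs])
    N = int(ns.sum())
    means = np.array([a.mean() for a in arrs])
    grand = np.concatenate(arrs).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_b, df_w = k - 1, N - k
    ms_w = ss_within / df_w
    if ms_w == 0:
        raise DegenerateDataError("zero within-group variance; F undefined")
    F = (ss_between / df_b) / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    omnibus = TestResult(statistic=float(F), df=(df_b, df_w), p_value=p, comparison="omnibus")

    pairwise = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(ms_w / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(means[i] - means[j]) / se
        p_q = float(sps.studentized_range.sf(q, k, df_w))
        pairwise.append(
            TestResult(
                statistic=float(q),
                df=(k, df_w),
                p_value=p_q,
                comparison=f"{labels[i]} vs {labels[j]}",
            )
        )
    return omnibus, pairwise


def _irls_logistic(x: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Newton/IRLS fit of P(y=1|x) = sigmoid(b0 + b1 x).

    Returns (beta, converged). Complete separation drives |beta| to
    infinity; the caller falls back to the raw scores (same ROC ordering).
    """
    x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H + 1e-12 * np.eye(2), grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + delta
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
            return beta, False
        if np.max(np.abs(delta)) < tol:
            return beta, True
    return beta, False


def _roc_sweep(scores: np.ndarray, y: np.ndarray):
    """ROC curve by sweeping a threshold over ``scores`` (higher = more
    positive); tied scores collapse to one operating point so the trapezoid
    credits them 0.5."""
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(yy)[distinct]
    fp = np.cumsum(1 - yy)[distinct]
    n_pos, n_neg = tp[-1], fp[-1]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return thresholds, fpr, tpr, auc


def mann_whitney_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Rank-based AUC: P(pos > neg) + 0.5 P(pos = neg), via midranks."""
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    alls = np.concatenate([pos, neg])
    ranks = sps.rankdata(alls)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_from_labels(scores_pos, scores_neg, positive_label: str = "pos") -> ROCResult:
    """ROC of a univariate logistic model separating two voxel populations.

    A logistic regression (intercept + map value) is fitted by IRLS and the
    curve swept over its predicted probabilities. The logistic link is
    monotone in the single covariate, so the AUC coincides with the
    Mann-Whitney statistic of the scores (in the fitted direction). Under
    complete separation the fit diverges and the raw scores are swept
    directly (identical curve).
    """
    pos = np.asarray(scores_pos, dtype=float).ravel()
    neg = np.asarray(scores_neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    scores = np.concatenate([pos, neg])
    y = np.r_[np.ones(pos.size), np.zeros(neg.size)]

    if np.all(scores == scores[0]):
        beta, converged = np.zeros(2), True
    else:
        beta, converged = _irls_logistic(scores, y)
    if converged:
        slope = beta[1]
        swept = scores if slope == 0 else np.sign(slope) * scores
        used_fallback = False
    else:
        # complete (or quasi-) separation: orient by the observed rank order
        raw_auc = mann_whitney_auc(pos, neg)
        swept = scores if raw_auc >= 0.5 else -scores
        used_fallback = True

    thresholds, fpr, tpr, auc = _roc_sweep(swept, y)
    return ROCResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
        positive_label=positive_label, used_fallback=used_fallback,
    )
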