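"""Cut-off derivation and diagnostic-performance statistics.

Given per-subject scores (the ROI StdDev) and reference labels this
module builds the empirical ROC curve, estimates the area under it
(AUROC) by the rank-based Mann–Whitney estimator with ties counted
one half, attaches the Hanley–McNeil standard error and a normal 95%
confidence interval, and picks the operating point maximizing the
Youden index J = sensitivity + specificity − 1.  Candidate thresholds
are the midpoints between consecutive distinct scores plus sentinels
beyond both extremes, matching the strict "score > threshold"
positivity rule, so a derived cut-off generally falls between
observed values.

A univariate logistic screen (intercept + one predictor, fitted by
iteratively reweighted least squares) and the plain two-group tests
(pooled-variance t, 2x2 Pearson chi-square) used for cohort
comparisons round out the module.  Closed-form binormal helpers (AUC
and the density-equality Youden optimum for two normal score
distributions) support theory-vs-simulation checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import expit

from ._exceptions import CalibrationError, FitError, StatsError

__all__ = [
    "ROCResult",
    "LogisticFit",
    "GroupComparison",
    "auroc",
    "roc_curve",
    "youden_from_rates",
    "sens_spec_at",
    "logistic_fit_univariate",
    "or_from_beta",
    "ttest_independent",
    "chi_square_proportions",
    "hanley_mcneil_se",
    "binormal_auc",
    "binormal_youden_cutoff",
]


@dataclass
class ROCResult:
    """Empirical ROC curve with AUROC and the Youden-optimal cut-off.

    ``points`` is a list of ``(fpr, tpr, threshold)`` triples ordered
    by non-decreasing false-positive rate; ``ci95`` is the normal-
    approximation 95% interval ``auc ± 1.96·auc_se`` clipped to [0, 1].
    """

    points: list[tuple[float, float, float]]
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    best_cutoff: float
    youden_j: float
    sens_at_best: float
    spec_at_best: float


@dataclass
class LogisticFit:
    """Univariate logistic screen: slope, Wald test and odds ratio."""

    beta: float
    se: float
    wald: float
    p: float
    odds_ratio: float
    converged: bool
    n_iter: int
    intercept: float = float("nan")
    intercept_se: float = float("nan")


@dataclass
class GroupComparison:
    """Two-group comparison: pooled t-test and/or 2x2 chi-square."""

    t_stat: float = float("nan")
    t_p: float = float("nan")
    chi2_stat: float = float("nan")
    chi2_p: float = float("nan")


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise CalibrationError("scores and labels must have equal length")
    pos = scores[labels == "pos"]
    neg = scores[labels == "neg"]
    if len(pos) == 0 or len(neg) == 0:
        raise CalibrationError(
            f"both classes required: {len(pos)} positive, {len(neg)} negative"
        )
    return pos, neg


def auroc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Rank-based (Mann–Whitney) AUROC with ties counted one half.

    Equals the trapezoidal area under the empirical ROC curve and the
    probability that a random positive outscores a random negative.
    """
    pos, neg = _split(scores, labels)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil AUROC standard error (exponential approximation)."""
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def youden_from_rates(sens: float, spec: float) -> float:
    """Youden index J = sensitivity + specificity − 1."""
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise CalibrationError(f"rates must lie in [0, 1], got sens={sens}, spec={spec}")
    return sens + spec - 1.0


def sens_spec_at(
    scores: Sequence[float], labels: Sequence[str], cutoff: float
) -> tuple[float, float]:
    """Sensitivity and specificity at a cut-off under strict positivity.

    Sensitivity is the fraction of positives with score strictly above
    the cut-off; specificity the fraction of negatives at or below it.
    """
    pos, neg = _split(scores, labels)
    sens = float(np.mean(pos > cutoff))
    spec = float(np.mean(neg <= cutoff))
    return sens, spec


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> ROCResult:
    """Empirical ROC curve, AUROC ± SE, and the Youden-optimal cut-off.

    Threshold candidates are midpoints between consecutive distinct
    scores plus one sentinel below the minimum and one above the
    maximum; J ties break toward higher specificity, then toward the
    lower threshold.
    """
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    thresholds = _candidate_thresholds(scores)

    # Descending thresholds -> non-decreasing (fpr, tpr).
    points: list[tuple[float, float, float]] = []
    best = None  # (j, spec, -threshold) lexicographic max
    for t in thresholds[::-1]:
        sens = float(np.mean(pos > t))
        spec = float(np.mean(neg <= t))
        points.append((1.0 - spec, sens, float(t)))
        key = (sens + spec - 1.0, spec, -t)
        if best is None or key > best[0]:
            best = (key, float(t), sens, spec)

    auc = auroc(scores, labels)
    se = hanley_mcneil_se(auc, len(pos), len(neg))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    _, best_t, sens_b, spec_b = best
    return ROCResult(
        points=points,
        auc=auc,
        auc_se=se,
        ci95=(lo, hi),
        best_cutoff=best_t,
        youden_j=sens_b + spec_b - 1.0,
        sens_at_best=sens_b,
        spec_at_best=spec_b,
    )


def or_from_beta(beta: float) -> float:
    """Odds ratio per unit of the predictor: exp(beta)."""
    return float(math.exp(beta))


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum(y*eta - log(1 + exp(eta))), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_fit_univariate(
    x: Sequence[float],
    y: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of one predictor plus intercept.

    Newton/IRLS iterations; convergence when the largest coefficient
    change drops below ``tol``.  Standard errors come from the inverse
    observed information.  Under complete separation the likelihood
    has no finite maximum: the fit is returned with
    ``converged=False`` and its outputs are not meaningful.

    Raises
    ------
    FitError
        When the predictor is constant or only one outcome is present.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D of equal length")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise FitError("y must be binary 0/1")
    if y.min() == y.max():
        raise FitError("both outcomes must be present")
    if np.ptp(x) == 0:
        raise FitError("predictor is constant")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    n_iter = 0
    cov = np.full((2, 2), np.nan)
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            try:
                cov = np.linalg.inv((X * w[:, None]).T @ X)
            except np.linalg.LinAlgError:
                converged = False
            break

    b = float(beta[1])
    se = float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else float("nan")
    wald = (b / se) ** 2 if (se and np.isfinite(se) and se > 0) else float("nan")
    pval = float(sps.chi2.sf(wald, df=1)) if np.isfinite(wald) else float("nan")
    return LogisticFit(
        beta=b,
        se=se,
        wald=wald,
        p=pval,
        odds_ratio=or_from_beta(b) if np.isfinite(b) else float("nan"),
        converged=converged,
        n_iter=n_iter,
        intercept=float(beta[0]),
        intercept_se=float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else float("nan"),
    )


def ttest_independent(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided pooled-variance (Student) independent t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(t_stat=float(res.statistic), t_p=float(res.pvalue))


def chi_square_proportions(k1: int, n1: int, k2: int, n2: int) -> GroupComparison:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Compares the proportions ``k1/n1`` vs ``k2/n2``.
    """
    if n1 <= 0 or n2 <= 0:
        raise StatsError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise StatsError("counts must satisfy 0 <= k <= n")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise StatsError("a margin of the 2x2 table is zero")
    exp = row @ col / obs.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return GroupComparison(chi2_stat=chi2, chi2_p=float(sps.chi2.sf(chi2, df=1)))


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC when both classes are normal:
    Phi((mu_pos − mu_neg) / sqrt(sd_pos² + sd_neg²))."""
    return float(sps.norm.cdf((mu_pos - mu_neg) / math.hypot(sd_pos, sd_neg)))


def binormal_youden_cutoff(
    mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float
) -> float:
    """Youden-optimal threshold for two normal score densities.

    At the optimum the class densities are equal; with unequal
    variances that is a quadratic in the threshold and the root
    maximizing J is returned.
    """
    if sd_pos <= 0 or sd_neg <= 0:
        raise CalibrationError("standard deviations must be positive")
    if math.isclose(sd_pos, sd_neg):
        return 0.5 * (mu_pos + mu_neg)
    a = 1.0 / sd_pos**2 - 1.0 / sd_neg**2
    b = -2.0 * (mu_pos / sd_pos**2 - mu_neg / sd_neg**2)
    c = (
        mu_pos**2 / sd_pos**2
        - mu_neg**2 / sd_neg**2
        + 2.0 * math.log(sd_pos / sd_neg)
    )
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise CalibrationError("no real density-equality point")
    roots = [(-b + s * math.sqrt(disc)) / (2.0 * a) for s in (+1.0, -1.0)]

    def j(t: float) -> float:
        sens = sps.norm.sf(t, loc=mu_pos, scale=sd_pos)
        spec = sps.norm.cdf(t, loc=mu_neg, scale=sd_neg)
        return float(sens + spec - 1.0)

    return max(roots, key=j)
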