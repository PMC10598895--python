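"""Validation statistics for the screening study.

Score orientation: the screening score is the expected glottal visibility V
in mm with *lower values indicating difficulty*, so every routine here takes
V directly and works on -V internally; thresholds are reported back on the V
scale (a patient is called positive when V <= threshold).

AUC is the Mann-Whitney probability (ties counted 1/2); its confidence
interval and the paired comparison of two markers use DeLong's
nonparametric covariance estimator.  Sensitivity/specificity intervals are
exact Clopper-Pearson.  The AUC-driven sample-size routine inverts a
two-sided z-test under Hanley-McNeil variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateLabelsError, RangeError


@dataclass(frozen=True)
class RocResult:
    """ROC summary of V as a screening marker for a binary outcome."""

    auc: float
    auc_ci: tuple[float, float]
    curve: list[tuple[float, float, float]]  # (1 - specificity, sensitivity, tau_mm)
    youden_threshold: float  # mm; positive call when V <= tau
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    n_positive: int
    n_negative: int


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise RangeError("scores", scores.shape, "1-D scores aligned with labels")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabelsError("degenerate-labels: both outcome classes required")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values on an orientation where higher = positive."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, level: float = 0.95) -> RocResult:
    """ROC analysis of V (mm, lower = more positive) against true labels.

    AUC by the Mann-Whitney identity with ties counted 1/2; CI by DeLong;
    the operating threshold by Youden's index (ties toward the more negative,
    more specific threshold) with exact Clopper-Pearson intervals for the
    sensitivity and specificity it attains.
    """
    pos_v, neg_v = _split(scores, labels)
    v10, v01, auc = _placements(-pos_v, -neg_v)
    se = float(np.sqrt(_delong_variance(v10, v01)))
    z = sps.norm.ppf(0.5 + level / 2.0)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    taus = _candidate_thresholds(np.concatenate([pos_v, neg_v]))
    curve = []
    best_j, best_tau = -np.inf, taus[0]
    for tau in taus:
        sens = float(np.mean(pos_v <= tau))
        fpr = float(np.mean(neg_v <= tau))
        curve.append((fpr, sens, float(tau)))
        j = sens - fpr
        if j > best_j + 1e-12:  # strict improvement; ties keep the smaller tau
            best_j, best_tau = j, float(tau)

    m, n = len(pos_v), len(neg_v)
    tp = int(np.sum(pos_v <= best_tau))
    tn = int(np.sum(neg_v > best_tau))
    return RocResult(
        auc=float(auc),
        auc_ci=ci,
        curve=curve,
        youden_threshold=best_tau,
        sensitivity=tp / m,
        specificity=tn / n,
        sensitivity_ci=binom_ci(tp, m, level),
        specificity_ci=binom_ci(tn, n, level),
        n_positive=m,
        n_negative=n,
    )


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus flanking cut-offs."""
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1]]])


def youden_threshold(roc: RocResult) -> float:
    """Threshold (mm) maximizing J = sensitivity + specificity - 1."""
    return roc.youden_threshold


def binom_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if trials < 1:
        raise RangeError("trials", trials, "trials >= 1")
    if not 0 <= successes <= trials:
        raise RangeError("successes", successes, "0 <= successes <= trials")
    if not 0.0 < level < 1.0:
        raise RangeError("level", level, "level in (0, 1)")
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method="beta")
    return float(lo), float(hi)


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong test for the difference of two AUCs on shared labels.

    Both score vectors are V-oriented (lower = positive).  Returns
    ``(auc_a, auc_b, p_value)`` with a two-sided p.
    """
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    v10a, v01a, auc_a = _placements(-pos_a, -neg_a)
    v10b, v01b, auc_b = _placements(-pos_b, -neg_b)
    m, n = len(v10a), len(v01a)
    var_a = _delong_variance(v10a, v01a)
    var_b = _delong_variance(v10b, v01b)
    cov = 0.0
    if m > 1:
        cov += float(np.cov(v10a, v10b, ddof=1)[0, 1]) / m
    if n > 1:
        cov += float(np.cov(v01a, v01b, ddof=1)[0, 1]) / n
    delta = auc_a - auc_b
    var = var_a + var_b - 2.0 * cov
    if var <= 1e-16:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci: tuple[float, float]
    corrected: bool  # Haldane-Anscombe 0.5 added to every cell


def odds_ratio(tp: int, fn: int, fp: int, tn: int, level: float = 0.95) -> OddsRatioResult:
    """2x2 odds ratio with a Woolf logit interval.

    When any cell is zero the Haldane-Anscombe correction (0.5 added to all
    cells) is applied and flagged.
    """
    cells = (tp, fn, fp, tn)
    if any(c < 0 for c in cells):
        raise RangeError("cells", cells, "non-negative counts")
    if (tp + fn == 0) or (fp + tn == 0) or (tp + fp == 0) or (fn + tn == 0):
        raise RangeError("cells", cells, "all-zero margin: odds ratio undefined")
    corrected = any(c == 0 for c in cells)
    a, b, c, d = ((x + 0.5) for x in cells) if corrected else cells
    est = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = sps.norm.ppf(0.5 + level / 2.0)
    ci = (float(est * np.exp(-z * se)), float(est * np.exp(z * se)))
    return OddsRatioResult(odds_ratio=float(est), ci=ci, corrected=corrected)


def _hanley_mcneil_var(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    return (
        auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc * auc) + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)


def sample_size_auc(
    auc_alt: float,
    auc_null: float,
    alpha: float = 0.05,
    power: float = 0.8,
    positive_fraction: float = 0.025,
    max_n: int = 1_000_000,
) -> int:
    """Smallest total n so a two-sided z-test of AUC = auc_null attains
    the target power at AUC = auc_alt under Hanley-McNeil variances,
    with n_pos = round(positive_fraction * n)."""
    if not 0.5 < auc_null < auc_alt < 1.0:
        raise RangeError("auc", (auc_null, auc_alt), "0.5 < auc_null < auc_alt < 1")
    if not 0.0 < positive_fraction <= 0.5:
        raise RangeError("positive_fraction", positive_fraction, "in (0, 0.5]")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise RangeError("alpha/power", (alpha, power), "in (0, 1)")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    for n in range(4, max_n + 1):
        n_pos = int(round(positive_fraction * n))
        n_neg = n - n_pos
        if n_pos < 2 or n_neg < 2:
            continue
        se0 = np.sqrt(_hanley_mcneil_var(auc_null, n_pos, n_neg))
        se1 = np.sqrt(_hanley_mcneil_var(auc_alt, n_pos, n_neg))
        achieved = sps.norm.cdf(((auc_alt - auc_null) - z_a * se0) / se1)
        if achieved >= power:
            return n
    raise RangeError("n", max_n, "no n up to max_n attains the target power")
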