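"""Paired model-comparison tests and percentile-based cohort stratification.

McNemar's test compares the accuracies of two classifiers on the same test
samples through their discordant counts b (A correct, B wrong) and c
(A wrong, B correct): the continuity-corrected chi-square statistic
(|b - c| - 1)^2 / (b + c) on 1 df, or the exact two-sided binomial test of
b against Binomial(b + c, 1/2).

DeLong's test compares AUROCs of two score vectors over the same labeled
samples.  The AUC is the Mann-Whitney estimator (ties credited 1/2); its
variance and the covariance between correlated AUCs come from the DeLong
structural components (placement values), giving a two-sided normal test,
including a single-model test against chance (AUC = 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedOutcomes",
    "GroupAssignment",
    "mcnemar_test",
    "delong_test",
    "delong_vs_chance",
    "auc_mann_whitney",
    "stratify_by_lesion_count",
]


@dataclass
class PairedOutcomes:
    """Per-sample correctness of two classifiers on a common test set."""

    correct_a: np.ndarray
    correct_b: np.ndarray

    def __post_init__(self) -> None:
        self.correct_a = np.asarray(self.correct_a, dtype=bool)
        self.correct_b = np.asarray(self.correct_b, dtype=bool)
        if self.correct_a.shape != self.correct_b.shape or self.correct_a.ndim != 1:
            raise ValueError("outcome vectors must be equal-length 1D")
        if len(self.correct_a) == 0:
            raise ValueError("at least one sample required")

    @property
    def discordant(self) -> tuple[int, int]:
        b = int(np.sum(self.correct_a & ~self.correct_b))
        c = int(np.sum(~self.correct_a & self.correct_b))
        return b, c


def mcnemar_test(outcomes: PairedOutcomes, mode: str = "chi2_cc") -> tuple[float, float]:
    """McNemar's test on paired classifier outcomes.

    ``mode="chi2_cc"``: continuity-corrected chi-square (statistic clamped
    at 0 when |b - c| < 1), p from chi2(1).  ``mode="exact"``: two-sided
    binomial, p = min(1, 2 * min(P(X <= b), P(X >= b))) with
    X ~ Binomial(b + c, 1/2); returns p = 1 when there are no discordant
    pairs (chi2 mode raises instead).
    """
    b, c = outcomes.discordant
    n = b + c
    if mode == "chi2_cc":
        if n == 0:
            raise ValueError("chi-square McNemar needs at least one discordant pair")
        stat = max(abs(b - c) - 1.0, 0.0) ** 2 / n
        return stat, float(sps.chi2.sf(stat, df=1))
    if mode == "exact":
        if n == 0:
            return 0.0, 1.0
        p = 2.0 * min(sps.binom.cdf(b, n, 0.5), sps.binom.sf(b - 1, n, 0.5))
        return float(min(b, c)), float(min(1.0, p))
    raise ValueError(f"unknown mode {mode!r}")


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC as the Mann-Whitney pair statistic, ties credited 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (len(pos) * len(neg)))


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the V10 (positives) and V01 (negatives) structural
    components of the DeLong variance estimator."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    ge = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = ge.mean(axis=1)  # per positive
    v01 = ge.mean(axis=0)  # per negative
    auc = float(ge.mean())
    return auc, v10, v01


def delong_vs_chance(scores, labels) -> tuple[float, float, float]:
    """Single-model DeLong test of AUC against 0.5.

    Returns (auc, z, two-sided p).  A degenerate variance (perfectly
    constant placements) yields p = 0 if AUC != 0.5 else 1.
    """
    auc, v10, v01 = _delong_placements(scores, labels)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    if var <= 0:
        z = np.inf if auc != 0.5 else 0.0
        return auc, float(z), 0.0 if auc != 0.5 else 1.0
    z = (auc - 0.5) / np.sqrt(var)
    return auc, float(z), float(2 * sps.norm.sf(abs(z)))


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """DeLong test comparing the AUROCs of two correlated score vectors.

    Both score vectors must be over the same samples/labels.  Returns
    (auc_a, auc_b, z, two-sided p); identical scores give z = 0, p = 1.
    """
    auc_a, v10_a, v01_a = _delong_placements(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    if var <= 0:
        if auc_a == auc_b:
            return auc_a, auc_b, 0.0, 1.0
        return auc_a, auc_b, np.inf, 0.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return auc_a, auc_b, float(z), float(2 * sps.norm.sf(abs(z)))


@dataclass
class GroupAssignment:
    """Percentile stratification of subjects by lesion count."""

    counts: np.ndarray
    group: np.ndarray  # "high" | "low" | "excluded" per subject
    hi_threshold: float
    lo_threshold: float

    def indices(self, which: str) -> np.ndarray:
        return np.nonzero(self.group == which)[0]


def stratify_by_lesion_count(
    counts, hi_pct: float = 75.0, lo_pct: float = 25.0
) -> GroupAssignment:
    """Split subjects into high/low groups by lesion-count percentiles.

    ``high``: counts strictly above the ``hi_pct`` percentile; ``low``:
    strictly below the ``lo_pct`` percentile; everything else excluded.
    Percentiles use the linear-interpolation quantile convention, so
    boundary subjects (count equal to a threshold) are excluded.
    """
    counts = np.asarray(counts)
    if len(counts) < 4:
        raise ValueError("stratification needs >= 4 subjects")
    hi = float(np.percentile(counts, hi_pct))
    lo = float(np.percentile(counts, lo_pct))
    group = np.full(len(counts), "excluded", dtype=object)
    group[counts > hi] = "high"
    group[counts < lo] = "low"
    if not np.any(group == "high") or not np.any(group == "low"):
        raise ValueError("degenerate cohort: an extreme group is empty")
    return GroupAssignment(
        counts=counts, group=group, hi_threshold=hi, lo_threshold=lo
    )
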