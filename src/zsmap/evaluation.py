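"""Statistical comparison layer.

Paired two-sided t-tests for Mask(-) vs Mask(+) regional values, ROC curves
with trapezoidal AUC, the Youden-index optimal cutoff with its diagnostic
accuracy, pooling of per-subject regional observations, one-way ANOVA with
Tukey-Kramer pairwise comparisons, and a paired-bootstrap test for AUC
differences between the masked and unmasked analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .roi import MissingRegionWarning, RegionStats

__all__ = [
    "ROCResult",
    "DegenerateTestError",
    "paired_t_test",
    "roc_analysis",
    "pool_region_observations",
    "compare_groups_anova",
    "compare_auc",
]


class DegenerateTestError(ValueError):
    pass


def paired_t_test(a, b) -> tuple[float, float]:
    """Classical paired Student t on the differences, two-sided p (df = n-1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateTestError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ROCResult:
    """ROC curve with AUC and the Youden-optimal operating point.

    Scores are Z values (higher = more abnormal); the positive class is the
    disease group.  A case is called positive when score >= threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    accuracy_at_cutoff: float  # percent
    n_pos: int
    n_neg: int

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of [0, 1]")

    @property
    def youden_index(self) -> float:
        i = int(np.argmin(np.abs(self.thresholds - self.youden_cutoff)))
        return float(self.sensitivity[i] + self.specificity[i] - 1.0)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def roc_analysis(scores, labels) -> ROCResult:
    """ROC curve over all unique thresholds, trapezoidal AUC, Youden cutoff.

    The trapezoidal AUC over every unique score threshold equals the
    normalized Mann-Whitney U statistic.  The Youden cutoff maximizes
    J = sensitivity + specificity - 1; ties are broken toward the lower
    threshold (the more sensitive rule).  Accuracy is (TP + TN)/n at that
    cutoff, in percent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D of equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTestError("ROC requires both classes present")

    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    # drop the leading artificial +inf threshold point for the operating table
    finite = np.isfinite(thr)
    thresholds = thr[finite]
    sens = tpr[finite]
    spec = 1.0 - fpr[finite]

    j = sens + spec - 1.0
    # tolerance so floating-point rounding cannot hide an exact tie in J
    best = np.flatnonzero(j >= j.max() - 1e-12)
    # thresholds are sorted decreasing; the lowest threshold is the last
    cut_i = int(best[-1])
    cutoff = float(thresholds[cut_i])
    pred = scores >= cutoff
    accuracy = 100.0 * float((pred == (labels == 1)).mean())
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=auc, youden_cutoff=cutoff, accuracy_at_cutoff=accuracy,
        n_pos=n_pos, n_neg=n_neg,
    )


def pool_region_observations(stats_by_subject: dict[str, list[RegionStats]],
                             group_by_subject: dict[str, str],
                             regions: list[str] | None = None) -> pd.DataFrame:
    """Pool per-subject bilateral regional Z-scores into one labeled score set.

    One observation per subject x region; a subject missing a region
    contributes its remaining regions, with a warning.  Returns a tidy frame
    with columns ``subject``, ``group``, ``region``, ``z``.
    """
    rows = []
    for subject, stats in stats_by_subject.items():
        by_region = {s.region: s for s in stats}
        wanted = regions if regions is not None else list(by_region)
        for region in wanted:
            if region not in by_region:
                warnings.warn(f"subject {subject} missing region {region}",
                              MissingRegionWarning)
                continue
            rows.append({
                "subject": subject,
                "group": group_by_subject[subject],
                "region": region,
                "z": by_region[region].mean_z,
            })
    return pd.DataFrame(rows, columns=["subject", "group", "region", "z"])


def compare_groups_anova(groups: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with Tukey-Kramer pairwise comparisons.

    Returns (F, omnibus p, pairwise table).  Tukey's honest significant
    difference in its unequal-n (Kramer) form handles the unbalanced
    diagnostic groups.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise DegenerateTestError("need >= 2 groups with >= 2 values each")
    f_stat, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * a.size for k, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return float(f_stat), float(p), table


def compare_auc(scores_a, scores_b, labels, n_boot: int = 2000,
                seed: int = 0) -> tuple[float, float]:
    """Paired bootstrap test for a difference in AUC on the same subjects.

    Resamples subjects (stratified by class, so both classes stay present),
    recomputes both AUCs per resample and returns (observed AUC difference
    b - a, two-sided bootstrap p).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("score sets and labels must align (same subjects)")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateTestError("both classes required")

    def _auc(s, idx):
        lab = labels[idx]
        fpr, tpr, _ = roc_curve(lab, s[idx], drop_intermediate=False)
        return float(np.trapezoid(tpr, fpr))

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size, replace=True),
                              rng.choice(neg, neg.size, replace=True)])
        diffs[i] = _auc(scores_b, idx) - _auc(scores_a, idx)
    observed = _auc(scores_b, np.arange(labels.size)) - _auc(scores_a, np.arange(labels.size))
    p_lo = (np.sum(diffs <= 0) + 1) / (n_boot + 1)
    p_hi = (np.sum(diffs >= 0) + 1) / (n_boot + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return float(observed), float(p)
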