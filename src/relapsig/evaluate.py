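"""ROC curves, AUC and bootstrap confidence intervals for LOO scores.

AUC is the tie-aware Mann-Whitney statistic (equivalently the trapezoidal
area under the empirical ROC curve, with tied scores stepped
simultaneously). Confidence intervals come from a stratified percentile
bootstrap by default, preserving the cohort's class balance in every
resample; a DeLong (asymptotic) interval is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve


def auc_score(scores: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)  # midranks handle ties
    r1 = float(np.sum(ranks[y == 1]))
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@dataclass
class RocResult:
    """ROC operating points with AUC and its confidence interval."""

    points: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float
    ci_low: float
    ci_high: float
    ci_level: float
    boot_reps: int
    seed: Optional[int]
    method: str = "bootstrap"
    n_redrawn: int = 0

    def summary(self) -> str:
        return (
            f"AUC {self.auc:.4f}  "
            f"{self.ci_level:.0%} CI [{self.ci_low:.4f}, {self.ci_high:.4f}] "
            f"({self.method}, reps={self.boot_reps})"
        )


def roc_points(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def bootstrap_ci(
    scores: np.ndarray,
    y: np.ndarray,
    reps: int = 2000,
    level: float = 0.95,
    seed: Optional[int] = None,
    stratified: bool = True,
) -> tuple[float, float, int]:
    """Percentile bootstrap interval for the AUC.

    Samples are resampled with replacement within each class (stratified),
    so every resample keeps the study's class balance and both classes are
    always present. With ``stratified=False`` a degenerate one-class
    resample is redrawn; the count of redraws is returned.
    """
    if reps < 100:
        raise ValueError("bootstrap needs reps >= 100")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    if idx1.size == 0 or idx0.size == 0:
        raise ValueError("both classes must be present")
    aucs = np.empty(reps)
    n_redrawn = 0
    for r in range(reps):
        if stratified:
            take = np.concatenate(
                [rng.choice(idx1, idx1.size), rng.choice(idx0, idx0.size)]
            )
        else:
            take = rng.choice(len(y), len(y))
            while np.unique(y[take]).size < 2:
                n_redrawn += 1
                take = rng.choice(len(y), len(y))
        aucs[r] = auc_score(scores[take], y[take])
    lo, hi = np.quantile(aucs, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi), n_redrawn


def delong_ci(
    scores: np.ndarray, y: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """DeLong asymptotic interval (midrank formulation), clipped to [0,1]."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    auc = (np.sum(all_r[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # placement of each positive among negatives
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = stats.norm.ppf((1 + level) / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_analysis(
    scores,
    y,
    reps: int = 2000,
    level: float = 0.95,
    seed: Optional[int] = None,
    method: str = "bootstrap",
) -> RocResult:
    """Full ROC evaluation of a score vector: points, AUC and CI."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    auc = auc_score(scores, y)
    if method == "bootstrap":
        lo, hi, n_redrawn = bootstrap_ci(scores, y, reps, level, seed)
    elif method == "delong":
        lo, hi = delong_ci(scores, y, level)
        n_redrawn = 0
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = min(lo, auc)
    hi = max(hi, auc)
    return RocResult(
        roc_points(scores, y), auc, lo, hi, level, reps, seed, method, n_redrawn
    )
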