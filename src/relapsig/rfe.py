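"""Linear-SVM recursive feature elimination with Monte-Carlo 2-fold CV.

The panel-selection rule follows the classic RFE recipe: train a linear
soft-margin SVM, rank features by squared weight, drop the worst, repeat.
At every surviving-set size the classifier is scored by repeated
stratified random halving (each half serves once as the test set), and the
selected panel is the smallest size attaining the maximum of the mean
accuracy curve — the minimal panel with maximal accuracy.

Feature standardization always uses training-fold statistics only, so no
information leaks from test folds into the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .config import PipelineConfig
from .containers import FeatureMatrix, labels_to_binary

try:  # low-overhead path into the same libsvm solver SVC wraps
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_FAST_LIBSVM = True
except (ImportError, AttributeError):  # pragma: no cover - sklearn internals
    _HAVE_FAST_LIBSVM = False


def _standardize(train: np.ndarray, *apply_to: np.ndarray):
    """Z-score columns by the training array's statistics (SD 0 -> 1)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train, *apply_to))


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Fit a soft-margin linear SVM; return (weights, bias).

    The decision function is f(x) = w.x + b with positive scores for class
    1. The per-feature RFE ranking criterion is w_i**2. ``X`` is expected
    standardized (training statistics only).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("cannot train an SVM on a single class")
    if classes.size > 2 or not np.isin(classes, [0, 1]).all():
        raise ValueError(f"labels must be binary 0/1, got classes {classes}")
    yf = np.ascontiguousarray(y, dtype=np.float64)
    if _HAVE_FAST_LIBSVM:
        out = _libsvm.fit(X, yf, svm_type=0, kernel="linear", C=float(C))
        sv, coef, intercept = out[1], out[3], out[4]
        # libsvm's binary orientation is the reverse of the positive-for-
        # class-1 convention; negate (as sklearn's SVC wrapper does)
        w = -(coef @ sv).ravel()
        b = -float(intercept[0])
        return w, b
    model = SVC(kernel="linear", C=C).fit(X, y)  # pragma: no cover - fallback
    return model.coef_.ravel(), float(model.intercept_[0])


def svm_predict(X: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """Class predictions (1 where the decision score is positive)."""
    return (X @ w + b > 0).astype(int)


def _stratified_halves(y: np.ndarray, rng: np.random.Generator):
    """One random stratified halving; returns (idx_d0, idx_d1)."""
    d0, d1 = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(
                f"class {cls} has {idx.size} sample(s); stratified halving needs >=2"
            )
        idx = rng.permutation(idx)
        half = (idx.size + 1) // 2
        d0.append(idx[:half])
        d1.append(idx[half:])
    return np.concatenate(d0), np.concatenate(d1)


def mc_two_fold_cv(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    reps: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Monte-Carlo 2-fold CV accuracies (2 per repetition).

    Each repetition draws one stratified random halving d0/d1, trains on
    d0 and tests on d1, then trains on d1 and tests on d0, so every sample
    is used for both training and validation in every repetition.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    accs = np.empty(2 * reps)
    for r in range(reps):
        i0, i1 = _stratified_halves(y, rng)
        for k, (tr, te) in enumerate(((i0, i1), (i1, i0))):
            Xtr, Xte = _standardize(X[tr], X[te])
            w, b = train_linear_svm(Xtr, y[tr], C)
            accs[2 * r + k] = float(np.mean(svm_predict(Xte, w, b) == y[te]))
    return accs


def loo_scores(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> tuple[np.ndarray, float]:
    """Leave-one-out decision scores and accuracy.

    Each sample is scored by an SVM trained on the remaining n-1 samples
    (standardized on those n-1 only). Raises if any training fold is
    single-class (possible only for tiny cohorts).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = len(y)
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            raise ValueError(
                f"LOO fold {i} is untrainable: training set has a single class"
            )
        Xtr, Xte = _standardize(X[mask], X[[i]])
        w, b = train_linear_svm(Xtr, y[mask], C)
        scores[i] = float((Xte @ w)[0] + b)
    accuracy = float(np.mean((scores > 0).astype(int) == y))
    return scores, accuracy


@dataclass
class RfeResults:
    """Outcome of one SVM-RFE run.

    ``elimination_order`` lists features in removal order (first removed
    first); ``ranking`` is the reverse (best feature first).
    ``accuracy_curve`` has one row per panel size k with the mean and SD
    of the MC-CV accuracies observed with the k longest-surviving
    features.
    """

    elimination_order: list[str]
    accuracy_curve: pd.DataFrame  # columns: k, mean_accuracy, sd_accuracy
    selected_k: int
    selected_panel: list[str]

    @property
    def ranking(self) -> list[str]:
        return self.elimination_order[::-1]

    def summary(self) -> str:
        curve = self.accuracy_curve.set_index("k")
        best = curve.loc[self.selected_k]
        lines = [
            "SVM-RFE results",
            "=" * 47,
            f"features considered : {len(self.elimination_order)}",
            f"selected panel size : {self.selected_k}",
            f"CV accuracy at k*   : {best['mean_accuracy']:.4f} "
            f"(SD {best['sd_accuracy']:.4f})",
            "panel (best first)  : " + ", ".join(self.selected_panel),
        ]
        return "\n".join(lines)


class SvmRfe:
    """Recursive feature elimination model for one omics data type.

    Parameters
    ----------
    matrix : FeatureMatrix (typically already significance-prefiltered)
    labels : sample id -> 'relapse' | 'relapse_free'
    config : PipelineConfig (svm_c, rfe_step, mc_reps are used)
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        labels: Mapping[str, str],
        config: Optional[PipelineConfig] = None,
    ):
        if matrix.shape[0] < 1:
            raise ValueError("RFE needs at least one feature")
        self.matrix = matrix
        self.feature_ids = matrix.feature_ids
        self.y = labels_to_binary(labels, matrix.sample_ids)
        self.config = config or PipelineConfig()

    def _eliminate(
        self, X: np.ndarray, y: np.ndarray, Xte=None, yte=None
    ) -> tuple[list[int], dict[int, float]]:
        """One full elimination pass on (X, y), already standardized.

        Returns the removal order (indices into X's columns) and, when a
        test fold is supplied, the test accuracy of the SVM trained on
        each surviving set, keyed by surviving-set size.
        """
        cfg = self.config
        ids = self.feature_ids
        alive = list(range(X.shape[1]))
        removed: list[int] = []
        acc_by_k: dict[int, float] = {}
        while alive:
            w, b = train_linear_svm(X[:, alive], y, cfg.svm_c)
            if Xte is not None:
                acc_by_k[len(alive)] = float(
                    np.mean(svm_predict(Xte[:, alive], w, b) == yte)
                )
            if len(alive) == 1:
                removed.append(alive[0])
                break
            crit = w**2
            # smallest criterion removed first; ties by lexicographic id
            order = sorted(range(len(alive)), key=lambda j: (crit[j], ids[alive[j]]))
            worst = order[: min(cfg.rfe_step, len(alive))]
            removed.extend(alive[j] for j in worst)
            for j in sorted(worst, reverse=True):
                del alive[j]
        return removed, acc_by_k

    def fit(self, seed: Optional[int] = None) -> RfeResults:
        """Run RFE with a nested Monte-Carlo 2-fold accuracy curve.

        To keep the accuracy-vs-panel-size curve free of selection bias,
        the elimination is re-run inside every training half and each
        surviving set is scored on the held-out half; the curve at size k
        therefore estimates the accuracy of a size-k panel selected on
        independent data. The reported panel is the curve's minimal
        argmax size applied to the elimination ranking computed on the
        full cohort.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        X_full = self.matrix.values.to_numpy().T  # samples x features
        y = self.y
        p = X_full.shape[1]
        acc_samples: dict[int, list[float]] = {k: [] for k in range(1, p + 1)}
        for _ in range(cfg.mc_reps):
            i0, i1 = _stratified_halves(y, rng)
            for tr, te in ((i0, i1), (i1, i0)):
                Xtr, Xte = _standardize(X_full[tr], X_full[te])
                _, acc_by_k = self._eliminate(Xtr, y[tr], Xte, y[te])
                for k, a in acc_by_k.items():
                    acc_samples[k].append(a)
        curve = pd.DataFrame(
            [
                (k, float(np.mean(v)), float(np.std(v, ddof=1)))
                for k, v in sorted(acc_samples.items())
                if v
            ],
            columns=["k", "mean_accuracy", "sd_accuracy"],
        )
        (Xs,) = _standardize(X_full)
        removed, _ = self._eliminate(Xs, y)
        eliminated = [self.feature_ids[j] for j in removed]
        best = curve["mean_accuracy"].max()
        selected_k = int(curve.loc[curve["mean_accuracy"] == best, "k"].min())
        selected_panel = eliminated[::-1][:selected_k]
        return RfeResults(eliminated, curve, selected_k, selected_panel)

    def loo_validate(self, panel: list[str]) -> tuple[pd.Series, float]:
        """LOO decision scores and accuracy for a selected panel."""
        if not panel:
            raise ValueError("panel must be non-empty")
        sub = self.matrix.restrict(panel)
        X = sub.values.to_numpy().T
        scores, acc = loo_scores(X, self.y, self.config.svm_c)
        return pd.Series(scores, index=sub.sample_ids, name="loo_score"), acc
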