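"""Per-feature two-sided Welch (unequal-variance) t-test prefiltering.

Each feature is tested for a group-mean difference between relapse and
relapse-free samples; features at p <= alpha form the shortlist passed to
SVM-RFE. Raw p-values are used by default (no multiple-testing
correction), with Benjamini-Hochberg available as an opt-in.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureMatrix, check_labels


def welch_statistics(a: np.ndarray, b: np.ndarray):
    """Vectorised Welch t, Welch-Satterthwaite df and two-sided p.

    ``a`` and ``b`` are features x samples arrays (NaN = missing). Features
    with fewer than two non-missing values in either group are untestable
    and get NaN throughout. Degenerate zero-variance features: equal means
    give t = 0, p = 1; unequal means give t = +/-inf, p = 0.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na = np.sum(~np.isnan(a), axis=1).astype(float)
    nb = np.sum(~np.isnan(b), axis=1).astype(float)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    testable = (na >= 2) & (nb >= 2)

    t = np.full(a.shape[0], np.nan)
    df = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = va / na + vb / nb
        diff = ma - mb
        tt = diff / np.sqrt(se2)
        dd = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))

    zero_var = testable & (se2 == 0)
    ok = testable & (se2 > 0)
    t[ok] = tt[ok]
    df[ok] = dd[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(tt[ok]), dd[ok])
    # both groups constant: identical means carry no evidence; different
    # means are infinitely strong under the model
    eq = zero_var & (diff == 0)
    ne = zero_var & (diff != 0)
    t[eq], df[eq], p[eq] = 0.0, na[eq] + nb[eq] - 2, 1.0
    t[ne] = np.sign(diff[ne]) * np.inf
    df[ne], p[ne] = na[ne] + nb[ne] - 2, 0.0
    return t, df, p


def welch_test(matrix: FeatureMatrix, labels: Mapping[str, str]) -> pd.DataFrame:
    """Welch test per feature; returns columns t, df, p, testable.

    Untestable features (fewer than two non-missing values in a group)
    carry NaN p and ``testable = False``; they are never passed downstream.
    """
    rel, free = check_labels(labels, matrix.sample_ids)
    a = matrix.values[rel].to_numpy()
    b = matrix.values[free].to_numpy()
    t, df, p = welch_statistics(a, b)
    return pd.DataFrame(
        {"t": t, "df": df, "p": p, "testable": ~np.isnan(p)},
        index=matrix.values.index,
    )


def filter_significant(table: pd.DataFrame, alpha: float, bh: bool = False) -> list[str]:
    """Feature ids with p <= alpha, preserving matrix order.

    With ``bh`` the threshold is applied to Benjamini-Hochberg adjusted
    p-values instead of raw ones.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    p = table["p"]
    if bh:
        p = benjamini_hochberg(p)
    keep = table.index[(p <= alpha) & table["testable"]]
    return list(keep)


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """BH-adjusted p-values; NaNs (untestable) are left NaN."""
    mask = p.notna()
    q = p.copy()
    pv = p[mask].to_numpy()
    m = len(pv)
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[mask] = out
    return q
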