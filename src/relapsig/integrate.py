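"""Multi-omics integration: combined matrix, random-forest ranking against
artificial contrasts, p-value tiering and the Kendall association network.

The ranking scheme plants one independently permuted copy of every real
feature ("artificial contrasts") into the matrix before growing each
forest. Contrasts are marginally identical to their sources but carry no
label information, so the distribution of contrast importances is an
empirical null for the real importances. Each real feature is compared,
across forest repetitions, against the configured quantile of that
repetition's contrast importances with a one-sided paired t-test; its
normalized score is its mean importance divided by the mean contrast
quantile. Importance is out-of-bag permutation importance (mean decrease
in OOB accuracy when the feature is permuted), averaged over trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .config import PipelineConfig
from .containers import CytobandMap, FeatureMatrix, ValidationError, labels_to_binary


def combine_panels(
    panels: Mapping[str, list[str]],
    matrices: Mapping[str, FeatureMatrix],
) -> FeatureMatrix:
    """Row-bind the per-type selected panels into one z-scored matrix.

    Feature ids are namespaced ``type:id``. Every matrix must cover the
    same sample set; rows are z-scored across samples.
    """
    ref_type = next(iter(panels))
    sample_ids = matrices[ref_type].sample_ids
    ref_set = set(sample_ids)
    rows, ids = [], []
    for dtype, panel in panels.items():
        if not panel:
            continue
        m = matrices[dtype]
        missing = sorted(ref_set - set(m.sample_ids))
        extra = sorted(set(m.sample_ids) - ref_set)
        if missing or extra:
            raise ValidationError(
                f"sample-set mismatch for {dtype}: missing {missing}, extra {extra}"
            )
        if len(set(panel)) != len(panel):
            dup = sorted({f for f in panel if panel.count(f) > 1})
            raise ValidationError(f"duplicate feature(s) in {dtype} panel: {dup}")
        sub = m.restrict(panel).values[sample_ids]
        for fid, row in sub.iterrows():
            ids.append(f"{dtype}:{fid}")
            rows.append(row.to_numpy())
    if len(set(ids)) != len(ids):
        raise ValidationError("namespaced feature ids collide across panels")
    X = np.asarray(rows, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s) in combined matrix; "
            "left as zeros after centring",
            stacklevel=2,
        )
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    values = pd.DataFrame(Z, index=ids, columns=sample_ids)
    return FeatureMatrix("combined", values)


def make_contrasts(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Artificial contrasts: one independently permuted copy per column."""
    n = X.shape[0]
    return np.column_stack([X[rng.permutation(n), j] for j in range(X.shape[1])])


def _oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean decrease in OOB accuracy per feature, averaged over trees.

    For each tree, all per-feature permuted copies of its OOB block are
    stacked into a single matrix so the tree predicts once instead of
    once per feature.
    """
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    classes = forest.classes_
    imp = np.zeros(p)
    n_trees = 0
    for est, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        m = int(oob.sum())
        if m == 0:
            continue
        Xo = X32[oob]
        yo = y[oob]
        tree = est.tree_

        def _acc(block: np.ndarray) -> np.ndarray:
            votes = tree.predict(np.ascontiguousarray(block))
            pred = classes[votes.reshape(votes.shape[0], -1).argmax(axis=1)]
            return (pred.reshape(-1, m) == yo).mean(axis=1)

        base = float(_acc(Xo)[0])
        # permuting a feature the tree never splits on cannot change its
        # predictions, so only the tree's own features need scoring
        used = np.unique(tree.feature)
        used = used[used >= 0]
        if used.size:
            big = np.tile(Xo, (used.size, 1))
            for r, j in enumerate(used):
                big[r * m : (r + 1) * m, j] = Xo[rng.permutation(m), j]
            imp[used] += base - _acc(big)
        n_trees += 1
    if n_trees == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return imp / n_trees


@dataclass
class RfAceResults:
    """Ranked features from the artificial-contrast forest analysis."""

    ranked: pd.DataFrame  # feature, data_type, score, p, rank
    contrast_quantiles: np.ndarray  # per forest repetition
    forests: int
    trees: int

    def summary(self, top: int = 10) -> str:
        head = self.ranked.head(top)
        lines = [
            "Random-forest artificial-contrast ranking",
            "=" * 47,
            f"forest repetitions : {self.forests}  (trees each: {self.trees})",
            f"features ranked    : {len(self.ranked)}",
            "",
            head.to_string(index=False,
                           formatters={"score": "{:.3f}".format,
                                       "p": "{:.3g}".format}),
        ]
        return "\n".join(lines)


class RfAce:
    """Artificial-contrast random-forest ranking model.

    Parameters
    ----------
    combined : the combined (z-scored, namespaced) FeatureMatrix
    labels : sample id -> 'relapse' | 'relapse_free'
    config : uses ace_forests, ace_trees, ace_contrast_quantile
    """

    def __init__(
        self,
        combined: FeatureMatrix,
        labels: Mapping[str, str],
        config: Optional[PipelineConfig] = None,
    ):
        self.matrix = combined
        self.y = labels_to_binary(labels, combined.sample_ids)
        self.config = config or PipelineConfig()
        if self.config.ace_forests < 2:
            raise ValueError("need at least two forest repetitions")
        if self.config.ace_trees < 10:
            raise ValueError("need at least ten trees per forest")

    def fit(self, seed: Optional[int] = None) -> RfAceResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        X = self.matrix.values.to_numpy().T  # samples x features
        n, p = X.shape
        ids = self.matrix.feature_ids
        const = X.std(axis=0) == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant feature(s); their importance is 0",
                stacklevel=2,
            )
        F, T, q = cfg.ace_forests, cfg.ace_trees, cfg.ace_contrast_quantile
        imp = np.zeros((F, p))
        cq = np.zeros(F)
        mtry = int(np.ceil(np.sqrt(p)))  # sqrt of real feature count
        for f in range(F):
            X_aug = np.hstack([X, make_contrasts(X, rng)])
            forest = RandomForestClassifier(
                n_estimators=T,
                max_features=mtry,
                bootstrap=True,
                n_jobs=cfg.n_threads,
                random_state=int(rng.integers(2**31)),
            ).fit(X_aug, self.y)
            all_imp = _oob_permutation_importance(forest, X_aug, self.y, rng)
            imp[f] = all_imp[:p]
            cq[f] = float(np.quantile(all_imp[p:], q))
        # one-sided paired comparison: feature importance vs the contrast
        # quantile of the same repetition
        d = imp - cq[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tt = stats.ttest_1samp(d, 0.0, axis=0, alternative="greater")
            pvals = np.asarray(tt.pvalue, dtype=float)
        dm = d.mean(axis=0)
        degenerate = ~np.isfinite(pvals)
        pvals[degenerate] = np.where(dm[degenerate] > 0, 0.0, 1.0)
        denom = max(float(cq.mean()), 1e-12)
        score = np.maximum(imp.mean(axis=0) / denom, 0.0)
        score[const] = 0.0
        pvals[const] = 1.0
        dtypes = [fid.split(":", 1)[0] if ":" in fid else "unknown" for fid in ids]
        ranked = pd.DataFrame(
            {"feature": ids, "data_type": dtypes, "score": score, "p": pvals}
        ).sort_values(["score", "feature"], ascending=[False, True], ignore_index=True)
        ranked["rank"] = np.arange(1, len(ranked) + 1)
        return RfAceResults(ranked, cq, F, T)


def select_top(
    ranked: pd.DataFrame, p_select: float = 0.01, p_top: float = 1e-30
) -> dict:
    """Nested significance tiers with per-data-type composition counts."""
    for name, val in (("p_select", p_select), ("p_top", p_top)):
        if not 0 < val <= 1:
            raise ValueError(f"{name} must be in (0,1]")
    sel = ranked[ranked["p"] <= p_select]
    top = ranked[ranked["p"] <= p_top]
    composition = sel.groupby("data_type")["feature"].count().to_dict()
    return {
        "selected": list(sel["feature"]),
        "top": list(top["feature"]),
        "composition": composition,
    }


def kendall_tau_p(x: np.ndarray, y: np.ndarray, n_exact_below: int = 10):
    """Tie-corrected Kendall tau-b with a p-value.

    Exact null enumeration for n below ``n_exact_below`` (falling back to
    the normal approximation when ties make the exact null invalid),
    normal approximation otherwise.
    """
    n = len(x)
    method = "exact" if n < n_exact_below else "asymptotic"
    try:
        res = stats.kendalltau(x, y, method=method)
    except ValueError:  # exact method rejects ties
        res = stats.kendalltau(x, y, method="asymptotic")
    tau = float(res.statistic)
    return (0.0 if np.isnan(tau) else tau), float(res.pvalue)


def kendall_network(
    combined: FeatureMatrix, alpha_edge: float = 0.01
) -> pd.DataFrame:
    """Pairwise Kendall tau-b association edges among selected features.

    Returns edges with p <= alpha_edge, one row per unordered pair:
    columns a, b, tau, p.
    """
    ids = combined.feature_ids
    if len(ids) < 2:
        raise ValueError("need at least two features to build a network")
    X = combined.values.to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            tau, p = kendall_tau_p(X[i], X[j])
            if p <= alpha_edge:
                rows.append((ids[i], ids[j], tau, p))
    return pd.DataFrame(rows, columns=["a", "b", "tau", "p"])


def map_coordinates(
    features: pd.DataFrame,
    gene_loci: Optional[pd.DataFrame] = None,
    bands: Optional[CytobandMap] = None,
) -> pd.DataFrame:
    """Genomic coordinates for mappable feature types.

    ``features`` needs columns feature (namespaced) and data_type.
    ``gene_loci`` is a BED-like frame (chrom, start, end, name) for genes
    and miRNAs; cytoband features resolve through ``bands``. Metabolite
    features are reported as unmapped by design.
    """
    loci: dict[str, tuple[str, int, int]] = {}
    if gene_loci is not None:
        if gene_loci["name"].duplicated().any():
            dup = gene_loci.loc[gene_loci["name"].duplicated(), "name"].tolist()
            raise ValidationError(f"duplicate locus annotation for: {dup}")
        for r in gene_loci.itertuples(index=False):
            loci[str(r.name)] = (str(r.chrom), int(r.start), int(r.end))
    rows = []
    for r in features.itertuples(index=False):
        bare = r.feature.split(":", 1)[1] if ":" in r.feature else r.feature
        coord = None
        if r.data_type in ("gene", "mirna"):
            coord = loci.get(bare)
        elif r.data_type == "cin_cytoband" and bands is not None:
            try:
                coord = bands.lookup(bare)
            except KeyError:
                coord = None
        if coord is None:
            rows.append((r.feature, "unmapped", "", ""))
        else:
            rows.append((r.feature, coord[0], coord[1], coord[2]))
    return pd.DataFrame(rows, columns=["feature", "chrom", "start", "end"])
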