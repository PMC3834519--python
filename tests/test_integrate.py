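"""Combined matrix, artificial-contrast ranking, tiers, Kendall network."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from relapsig import (
    PipelineConfig,
    RfAce,
    ValidationError,
    combine_panels,
    kendall_network,
    map_coordinates,
    select_top,
)
from relapsig.containers import CytobandMap, FeatureMatrix
from relapsig.integrate import kendall_tau_p, make_contrasts

from conftest import matrix_from_array


def tau_b_brute_force(x, y):
    """O(n^2) pair counting with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return 0.0 if denom == 0 else (conc - disc) / denom


class TestCombinePanels:
    def _fixtures(self, labels40):
        rng = np.random.default_rng(0)
        m1 = matrix_from_array(rng.normal(size=(5, 40)), "gene", "G",
                               sample_ids=list(labels40))
        m2 = matrix_from_array(rng.normal(size=(4, 40)), "mirna", "M",
                               sample_ids=list(labels40))
        return {"gene": m1, "mirna": m2}

    def test_dimensions_and_namespacing(self, labels40):
        mats = self._fixtures(labels40)
        out = combine_panels(
            {"gene": ["G001", "G002"], "mirna": ["M001"]}, mats
        )
        assert out.shape == (3, 40)
        assert out.feature_ids == ["gene:G001", "gene:G002", "mirna:M001"]

    def test_rows_are_zscored(self, labels40):
        mats = self._fixtures(labels40)
        out = combine_panels({"gene": ["G001", "G003"]}, mats)
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_duplicate_panel_entry_rejected(self, labels40):
        mats = self._fixtures(labels40)
        with pytest.raises(ValidationError, match="duplicate"):
            combine_panels({"gene": ["G001", "G001"]}, mats)

    def test_sample_mismatch_lists_missing(self, labels40):
        mats = self._fixtures(labels40)
        mats["mirna"] = FeatureMatrix(
            "mirna", mats["mirna"].values.iloc[:, :30]
        )
        with pytest.raises(ValidationError, match="missing"):
            combine_panels({"gene": ["G001"], "mirna": ["M001"]}, mats)


class TestContrasts:
    def test_each_contrast_is_a_permutation_of_its_source(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 6))
        C = make_contrasts(X, rng)
        assert C.shape == X.shape
        for j in range(6):
            np.testing.assert_array_equal(np.sort(C[:, j]), np.sort(X[:, j]))


class TestRfAce:
    def test_identical_seed_reproduces_ranking(self, labels40):
        rng = np.random.default_rng(1)
        fm = matrix_from_array(rng.normal(size=(30, 40)), "combined", "gene:F",
                               sample_ids=list(labels40))
        cfg = PipelineConfig(ace_forests=4, ace_trees=20, seed=0)
        r1 = RfAce(fm, labels40, cfg).fit(seed=5)
        r2 = RfAce(fm, labels40, cfg).fit(seed=5)
        pd.testing.assert_frame_equal(r1.ranked, r2.ranked)

    def test_planted_separator_ranks_first_with_tiny_p(self, labels40, y40):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 40))
        X[0] = 4.0 * y40 + 0.2 * rng.normal(size=40)
        fm = matrix_from_array(X, "combined", "gene:F", sample_ids=list(labels40))
        res = RfAce(fm, labels40, PipelineConfig(seed=0)).fit(seed=1)
        assert res.ranked.iloc[0]["feature"] == "gene:F001"
        assert res.ranked.iloc[0]["p"] <= 1e-4
        assert res.ranked.iloc[0]["rank"] == 1

    def test_constant_feature_scores_zero_with_warning(self, labels40):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 40))
        X[4] = 1.0
        fm = matrix_from_array(X, "combined", "gene:F", sample_ids=list(labels40))
        cfg = PipelineConfig(ace_forests=3, ace_trees=15, seed=0)
        with pytest.warns(UserWarning, match="constant"):
            res = RfAce(fm, labels40, cfg).fit(seed=0)
        row = res.ranked.set_index("feature").loc["gene:F005"]
        assert row["score"] == 0.0 and row["p"] == 1.0

    def test_scores_nonnegative_and_ranks_a_permutation(self, labels40):
        rng = np.random.default_rng(9)
        fm = matrix_from_array(rng.normal(size=(25, 40)), "combined", "gene:F",
                               sample_ids=list(labels40))
        cfg = PipelineConfig(ace_forests=3, ace_trees=15, seed=0)
        res = RfAce(fm, labels40, cfg).fit(seed=2)
        assert (res.ranked["score"] >= 0).all()
        assert sorted(res.ranked["rank"]) == list(range(1, 26))
        assert (res.ranked["score"].diff().dropna() <= 1e-12).all()  # descending

    def test_ranking_stable_when_forests_doubled(self, labels40, y40):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 40))
        for i in range(5):  # a few informative features of varying strength
            X[i] += (1.0 + 0.5 * i) * y40
        fm = matrix_from_array(X, "combined", "gene:F", sample_ids=list(labels40))
        r1 = RfAce(fm, labels40, PipelineConfig(ace_forests=20, seed=0)).fit(seed=3)
        r2 = RfAce(fm, labels40, PipelineConfig(ace_forests=40, seed=0)).fit(seed=4)
        merged = r1.ranked.merge(r2.ranked, on="feature")
        rho = stats.spearmanr(merged["score_x"], merged["score_y"]).statistic
        assert rho >= 0.9


class TestSelectTop:
    def _ranked(self, ps):
        return pd.DataFrame(
            {
                "feature": [f"gene:F{i}" for i in range(len(ps))],
                "data_type": ["gene"] * len(ps),
                "score": np.linspace(1, 0.1, len(ps)),
                "p": ps,
                "rank": range(1, len(ps) + 1),
            }
        )

    def test_nested_tiers(self):
        out = select_top(self._ranked([1e-40, 1e-3, 0.5]), 0.01, 1e-30)
        assert out["selected"] == ["gene:F0", "gene:F1"]
        assert out["top"] == ["gene:F0"]
        assert set(out["top"]) <= set(out["selected"])

    def test_all_null_gives_empty_tiers(self):
        out = select_top(self._ranked([1.0, 1.0]), 0.01, 1e-30)
        assert out["selected"] == [] and out["top"] == []

    def test_composition_sums_to_selected_size(self):
        out = select_top(self._ranked([0.001, 0.005, 0.5]), 0.01, 1e-30)
        assert sum(out["composition"].values()) == len(out["selected"])


class TestKendall:
    def test_hand_counted_example(self):
        tau, _ = kendall_tau_p(np.array([1, 2, 3, 4]), np.array([1, 2, 4, 3]))
        assert tau == pytest.approx(2 / 3, abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 16))
            x = rng.choice([0.0, 1.0, 2.0, 3.5, 9.0], size=n)
            y = rng.choice([0.0, 1.0, 2.0], size=n)
            tau, _ = kendall_tau_p(x, y)
            assert tau == pytest.approx(tau_b_brute_force(x, y), abs=1e-10)

    def test_duplicated_feature_has_tau_one(self, labels40):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        fm = matrix_from_array(np.vstack([x, x]), "combined", "gene:F",
                               sample_ids=list(labels40))
        edges = kendall_network(fm, alpha_edge=0.05)
        assert len(edges) == 1
        assert edges.loc[0, "tau"] == pytest.approx(1.0)

    def test_null_edge_rate_controlled(self, labels40):
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            fm = matrix_from_array(rng.normal(size=(12, 40)), "combined", "gene:F",
                                   sample_ids=list(labels40))
            edges = kendall_network(fm, alpha_edge=0.01)
            rates.append(len(edges) / 66)
        assert np.mean(rates) <= 0.03


class TestMapCoordinates:
    def test_mapping_by_feature_type(self):
        features = pd.DataFrame(
            {
                "feature": ["gene:TP53", "serum_pos:SPOS_mz0001", "cin_cytoband:1p1"],
                "data_type": ["gene", "serum_pos", "cin_cytoband"],
            }
        )
        loci = pd.DataFrame(
            {"chrom": ["17"], "start": [7_500_000], "end": [7_520_000],
             "name": ["TP53"]}
        )
        bands = CytobandMap(
            pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100],
                          "name": ["1p1"]})
        )
        out = map_coordinates(features, loci, bands).set_index("feature")
        assert out.loc["gene:TP53", "chrom"] == "17"
        assert out.loc["serum_pos:SPOS_mz0001", "chrom"] == "unmapped"
        assert out.loc["cin_cytoband:1p1", "start"] == 0

    def test_duplicate_annotation_rejected(self):
        features = pd.DataFrame(
            {"feature": ["gene:A"], "data_type": ["gene"]}
        )
        loci = pd.DataFrame(
            {"chrom": ["1", "2"], "start": [0, 0], "end": [10, 10],
             "name": ["A", "A"]}
        )
        with pytest.raises(ValidationError, match="duplicate"):
            map_coordinates(features, loci)
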