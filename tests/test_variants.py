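"""Variant filtering cascade, Fisher burden test, gene-set aggregation."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from relapsig import (
    AnnotatedVariantTable,
    filter_deleterious,
    gene_burden,
    relapse_exclusive,
    set_aggregate,
)


def make_table(rows, genotypes, samples):
    variants = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                 "deleterious", "af"],
    )
    return AnnotatedVariantTable(
        variants, pd.DataFrame(genotypes, columns=samples, dtype=np.int8)
    )


def labels_for(samples, n_relapse):
    return {
        s: ("relapse" if i < n_relapse else "relapse_free")
        for i, s in enumerate(samples)
    }


def fisher_two_sided_oracle(a, b, c, d):
    """Point-probability two-sided Fisher p by exhausting fixed margins."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def hyper(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = hyper(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = hyper(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


TOY_ROWS = [
    # (qualifies?) consequence x deleterious combinations
    ("1", 100, "A", "G", "G1", "missense_variant", True, 0.01),      # yes
    ("1", 200, "A", "G", "G1", "missense_variant", False, 0.01),     # no: benign
    ("1", 300, "A", "G", "G2", "synonymous_variant", True, 0.01),    # no: silent
    ("1", 400, "A", "G", "G2", "stop_gained", True, np.nan),         # yes
    ("1", 500, "A", "G", "G3", "intron_variant", True, 0.01),        # no
    ("1", 600, "A", "G", "G3", "frameshift_variant", True, 0.2),     # yes
    ("1", 700, "A", "G", "G4", "3_prime_UTR_variant", False, 0.01),  # no
    ("1", 800, "A", "G", "G4", "splice_donor_variant", True, 0.01),  # yes
    ("1", 900, "A", "G", "G5", "missense_variant", False, np.nan),   # no
    ("1", 950, "A", "G", "G5", "synonymous_variant", False, 0.3),    # no
]


class TestFilterDeleterious:
    def test_toy_fixture_keeps_exactly_the_qualifying_four(self):
        samples = ["A", "B"]
        gt = np.ones((10, 2), dtype=np.int8)
        out = filter_deleterious(make_table(TOY_ROWS, gt, samples))
        assert out.n_variants == 4
        assert list(out.variants["pos"]) == [100, 400, 600, 800]

    def test_missing_annotation_column_named(self):
        t = make_table(TOY_ROWS[:1], np.ones((1, 1), dtype=np.int8), ["A"])
        t.variants = t.variants.drop(columns=["deleterious"])
        with pytest.raises(KeyError, match="deleterious"):
            filter_deleterious(t)


class TestRelapseExclusive:
    def test_carrier_patterns(self):
        samples = [f"S{i}" for i in range(6)]
        labels = labels_for(samples, 3)
        rows = [TOY_ROWS[0]] * 3
        gt = np.array(
            [
                [1, 1, 1, 0, 0, 0],   # relapse-only -> kept
                [1, 1, 1, 1, 0, 0],   # one free carrier -> removed
                [-1, -1, -1, -1, -1, -1],  # all missing -> removed
            ],
            dtype=np.int8,
        )
        out = relapse_exclusive(make_table(rows, gt, samples), labels)
        assert out.n_variants == 1
        assert list(out.genotypes.iloc[0]) == [1, 1, 1, 0, 0, 0]

    def test_commutes_with_deleterious_filter(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(8)]
        labels = labels_for(samples, 4)
        rows = [TOY_ROWS[i % len(TOY_ROWS)] for i in range(20)]
        gt = rng.integers(-1, 2, size=(20, 8)).astype(np.int8)
        t = make_table(rows, gt, samples)
        a = relapse_exclusive(filter_deleterious(t), labels)
        b = filter_deleterious(relapse_exclusive(t, labels))
        pd.testing.assert_frame_equal(a.variants, b.variants)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)


class TestGeneBurden:
    def _cohort(self, carriers_rel, carriers_free, af=0.01):
        samples = [f"S{i:02d}" for i in range(40)]
        labels = labels_for(samples, 20)
        gt = np.zeros((1, 40), dtype=np.int8)
        gt[0, :carriers_rel] = 1
        gt[0, 20 : 20 + carriers_free] = 1
        rows = [("1", 100, "A", "G", "G1", "missense_variant", True, af)]
        return make_table(rows, gt, samples), labels

    def test_eight_vs_zero_matches_hypergeometric_oracle(self):
        t, labels = self._cohort(8, 0)
        out = gene_burden(t, labels)
        # one-sided tail: all 8 carriers in the relapse arm
        one_sided = comb(20, 8) / comb(40, 8)
        assert one_sided == pytest.approx(1.638e-3, abs=2e-6)
        assert out.loc[0, "p"] == pytest.approx(
            fisher_two_sided_oracle(8, 12, 0, 20), abs=1e-12
        )

    def test_no_carriers_anywhere_gives_p_one(self):
        t, labels = self._cohort(0, 0)
        assert gene_burden(t, labels).loc[0, "p"] == 1.0

    def test_extreme_table_attains_minimum_over_fixed_margins(self):
        t, labels = self._cohort(20, 0)
        p = gene_burden(t, labels).loc[0, "p"]
        # smallest attainable two-sided p at margins (20,20|20,20)
        assert p == pytest.approx(fisher_two_sided_oracle(20, 0, 0, 20), rel=1e-10)
        for a in range(21):
            assert p <= fisher_two_sided_oracle(a, 20 - a, 20 - a, a) + 1e-15

    def test_common_variants_excluded_by_af_cutoff(self):
        t, labels = self._cohort(8, 0, af=0.3)
        out = gene_burden(t, labels, af_cutoff=0.05)
        assert len(out) == 0

    def test_cohort_af_fallback_when_annotation_missing(self):
        t, labels = self._cohort(1, 0, af=np.nan)  # cohort AF = 1/80 < 0.05
        assert len(gene_burden(t, labels)) == 1

    def test_carrier_counts_invariant_to_variant_order(self):
        rng = np.random.default_rng(5)
        samples = [f"S{i}" for i in range(10)]
        labels = labels_for(samples, 5)
        rows = [
            ("1", 100 + i, "A", "G", f"G{i % 3}", "missense_variant", True, 0.01)
            for i in range(9)
        ]
        gt = rng.integers(0, 2, size=(9, 10)).astype(np.int8)
        t = make_table(rows, gt, samples)
        perm = rng.permutation(9)
        t2 = make_table([rows[i] for i in perm], gt[perm], samples)
        b1 = gene_burden(t, labels)
        b2 = gene_burden(t2, labels)
        pd.testing.assert_frame_equal(b1, b2)


class TestSetAggregate:
    def _toy(self):
        samples = [f"S{i}" for i in range(6)]
        labels = labels_for(samples, 3)
        rows = [
            ("1", 100 + i, "A", "G", g, "missense_variant", True, 0.01)
            for i, g in enumerate(["G1", "G2", "G3", "G4", "G5"])
        ]
        gt = np.zeros((5, 6), dtype=np.int8)
        gt[:, 0] = 1  # one relapse sample carries everything
        return make_table(rows, gt, samples), labels

    def test_hypergeometric_enrichment_against_oracle(self):
        t, labels = self._toy()
        background = [f"G{i}" for i in range(1, 21)]
        out = set_aggregate(t, labels, {"setA": ["G1", "G2"]}, background)
        row = out.iloc[0]
        assert row["n_genes"] == 2 and row["n_variants"] == 2
        # oracle: P(overlap >= 2) drawing 2 set genes from 20 with 5 hits
        expect = (comb(5, 2) * comb(15, 0)) / comb(20, 2)
        expect += 0  # only x=2 possible at N=2 beyond x>=2
        assert row["p"] == pytest.approx(expect, abs=1e-12)

    def test_disjoint_set_is_null(self):
        t, labels = self._toy()
        out = set_aggregate(t, labels, {"setB": ["GX", "GY"]})
        assert out.loc[0, "n_genes"] == 0
        assert out.loc[0, "p"] == 1.0

    def test_controls_column_all_zero_after_relapse_exclusive(self):
        rng = np.random.default_rng(2)
        samples = [f"S{i}" for i in range(10)]
        labels = labels_for(samples, 5)
        rows = [
            ("1", 100 + i, "A", "G", f"G{i}", "missense_variant", True, 0.01)
            for i in range(8)
        ]
        gt = rng.integers(0, 2, size=(8, 10)).astype(np.int8)
        t = relapse_exclusive(make_table(rows, gt, samples), labels)
        sets = {"s1": ["G0", "G1", "G2"], "s2": ["G3", "G4"], "s3": ["G5", "G6", "G7"]}
        out = set_aggregate(t, labels, sets, background=[f"G{i}" for i in range(8)])
        assert (out["n_controls"] == 0).all()

    def test_empty_background_rejected(self):
        t, labels = self._toy()
        with pytest.raises(ValueError, match="background"):
            set_aggregate(t, labels, {"s": ["G1"]}, background=[])
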