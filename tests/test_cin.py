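"""CIN index: closed-form cases, per-base brute-force oracle, invariants."""

import numpy as np
import pandas as pd
import pytest

from relapsig import CytobandMap, SegmentProfile, ValidationError
from relapsig.cin import chromosome_cin, cin_matrix, cytoband_cin, naive_segment


def bands_df(rows):
    return CytobandMap(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def profile(sample, rows):
    return SegmentProfile(
        sample, pd.DataFrame(rows, columns=["chrom", "start", "end", "log2_ratio"])
    )


def cin_per_base(segments, band_start, band_end, t_gain, t_loss):
    """Brute-force oracle: accumulate gain/loss base by base."""
    gain = loss = 0.0
    for pos in range(band_start, band_end):
        for _, s in segments.iterrows():
            if s["start"] <= pos < s["end"]:
                a = s["log2_ratio"]
                if a >= t_gain:
                    gain += a
                elif a <= -t_loss:
                    loss += -a
                break
    L = band_end - band_start
    return gain / L, loss / L


class TestCytobandCin:
    def test_neutral_genome_gives_zero_everywhere(self):
        bands = bands_df([("1", 0, 100, "1p1"), ("1", 100, 200, "1q1")])
        p = profile("A", [("1", 0, 200, 0.05)])
        out = cytoband_cin(p, bands, 0.2, 0.2)
        assert (out == 0).all().all()

    def test_half_band_amplification(self):
        bands = bands_df([("1", 0, 100, "1p1")])
        p = profile("A", [("1", 0, 50, 1.0)])
        out = cytoband_cin(p, bands, 0.2, 0.2)
        assert out.loc["1p1", "gain_index"] == pytest.approx(0.5)
        assert out.loc["1p1", "loss_index"] == 0.0

    def test_matches_per_base_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_bands = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(1, 60), 2 * n_bands, replace=False))
            band_rows = [
                ("1", int(bounds[2 * i]), int(bounds[2 * i + 1]), f"b{i}")
                for i in range(n_bands)
            ]
            bands = bands_df(band_rows)
            lo, hi = int(bounds[0]), int(bounds[-1])
            n_seg = int(rng.integers(0, 6))
            cuts = np.sort(rng.choice(np.arange(lo, hi + 1), min(2 * n_seg, hi - lo),
                                      replace=False))
            seg_rows = []
            for i in range(len(cuts) // 2):
                s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
                if s < e:
                    seg_rows.append(("1", s, e, float(rng.normal(0, 0.5))))
            p = profile("A", seg_rows)
            out = cytoband_cin(p, bands, 0.2, 0.2)
            for _, b in bands.records.iterrows():
                g, l = cin_per_base(p.segments, b["start"], b["end"], 0.2, 0.2)
                assert out.loc[b["name"], "gain_index"] == pytest.approx(g, abs=1e-12)
                assert out.loc[b["name"], "loss_index"] == pytest.approx(l, abs=1e-12)

    def test_raising_gain_threshold_never_increases_gain(self):
        bands = bands_df([("1", 0, 100, "1p1")])
        p = profile("A", [("1", 0, 60, 0.3), ("1", 60, 100, 0.7)])
        g1 = cytoband_cin(p, bands, 0.2, 0.2).loc["1p1", "gain_index"]
        g2 = cytoband_cin(p, bands, 0.5, 0.2).loc["1p1", "gain_index"]
        assert g2 <= g1

    def test_splitting_a_segment_changes_nothing(self):
        bands = bands_df([("1", 0, 100, "1p1"), ("1", 100, 180, "1q1")])
        p1 = profile("A", [("1", 10, 150, 0.9)])
        p2 = profile("A", [("1", 10, 77, 0.9), ("1", 77, 150, 0.9)])
        pd.testing.assert_frame_equal(
            cytoband_cin(p1, bands), cytoband_cin(p2, bands)
        )

    def test_segment_beyond_bounds_rejected(self):
        bands = bands_df([("1", 0, 100, "1p1")])
        p = profile("A", [("1", 50, 150, 0.5)])
        with pytest.raises(ValidationError, match="beyond"):
            cytoband_cin(p, bands)

    def test_unknown_chromosome_rejected(self):
        bands = bands_df([("1", 0, 100, "1p1")])
        p = profile("A", [("2", 0, 10, 0.5)])
        with pytest.raises(ValidationError, match="naming"):
            cytoband_cin(p, bands)


class TestChromosomeCin:
    def test_fully_amplified_chromosome(self):
        bands = bands_df([("1", 0, 100, "1p1"), ("1", 100, 200, "1q1")])
        p = profile("A", [("1", 0, 200, 1.0)])
        out = chromosome_cin(p, bands, 0.2, 0.2)
        assert out.loc["1", "gain_index"] == pytest.approx(1.0)

    def test_empty_profile_gives_zeros(self):
        bands = bands_df([("1", 0, 100, "1p1")])
        p = profile("A", [])
        assert (chromosome_cin(p, bands) == 0).all().all()

    def test_equals_length_weighted_band_average_on_contiguous_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cuts = np.sort(rng.choice(np.arange(1, 100), 3, replace=False))
            edges = [0, *map(int, cuts), 120]
            bands = bands_df(
                [("1", edges[i], edges[i + 1], f"b{i}") for i in range(4)]
            )
            seg_rows = []
            pos = 0
            while pos < 120:
                end = int(min(120, pos + rng.integers(5, 50)))
                seg_rows.append(("1", pos, end, float(rng.normal(0, 0.5))))
                pos = end
            p = profile("A", seg_rows)
            per_band = cytoband_cin(p, bands)
            lengths = (bands.records["end"] - bands.records["start"]).to_numpy()
            weighted = (
                per_band["total_index"].to_numpy() * lengths / lengths.sum()
            ).sum()
            whole = chromosome_cin(p, bands).loc["1", "total_index"]
            assert whole == pytest.approx(weighted, abs=1e-12)


class TestCinMatrix:
    def test_matrix_shape_and_channel_additivity(self):
        bands = bands_df(
            [("1", 0, 100, "1p1"), ("1", 100, 200, "1q1"), ("2", 0, 150, "2p1")]
        )
        profiles = [
            profile("A", [("1", 0, 200, 0.8), ("2", 0, 150, -0.5)]),
            profile("B", [("1", 0, 100, 0.05)]),
        ]
        total = cin_matrix(profiles, bands, channel="total")
        gain = cin_matrix(profiles, bands, channel="gain")
        loss = cin_matrix(profiles, bands, channel="loss")
        assert total.shape == (3, 2)
        np.testing.assert_allclose(
            total.values.to_numpy(),
            gain.values.to_numpy() + loss.values.to_numpy(),
            atol=1e-15,
        )

    def test_duplicate_sample_rejected(self):
        bands = bands_df([("1", 0, 100, "1p1")])
        p = profile("A", [])
        with pytest.raises(ValidationError, match="duplicate"):
            cin_matrix([p, p], bands)


class TestNaiveSegment:
    def test_windows_receive_window_means(self):
        pos = np.array([100, 200, 1_000_100])
        vals = np.array([1.0, 3.0, 5.0])
        seg = naive_segment(pos, vals, "1", window=1_000_000)
        assert len(seg) == 2
        assert seg.loc[0, "log2_ratio"] == pytest.approx(2.0)
        assert seg.loc[1, "log2_ratio"] == pytest.approx(5.0)
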