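"""Chromosomal-instability (CIN) indices from copy-number segments.

For a genomic region B of length L (a cytoband or a whole chromosome) and
a sample's piecewise-constant log2-ratio segments, the package defines

    gain_index(B) = sum over segments s with a_s >= t_gain  of a_s  * |s n B| / L
    loss_index(B) = sum over segments s with a_s <= -t_loss of |a_s| * |s n B| / L
    total_index(B) = gain_index(B) + loss_index(B)

i.e. an amplitude-weighted, length-normalized burden of gains and losses.
Unsegmented bases contribute nothing. The per-sample indices over all
cytobands form a feature matrix that flows into the same significance
filter and SVM-RFE machinery as the expression data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CytobandMap, FeatureMatrix, SegmentProfile, ValidationError


def _validate_profile_against_map(profile: SegmentProfile, bands: CytobandMap) -> None:
    spans = {
        chrom: (int(grp["start"].min()), int(grp["end"].max()))
        for chrom, grp in bands.records.groupby("chrom", sort=False)
    }
    for seg in profile.segments.itertuples(index=False):
        if seg.chrom not in spans:
            raise ValidationError(
                f"sample {profile.sample_id}: segment chromosome {seg.chrom!r} "
                "not present in the cytoband map (naming mismatch?)"
            )
        lo, hi = spans[seg.chrom]
        if seg.start < lo or seg.end > hi:
            raise ValidationError(
                f"sample {profile.sample_id}: segment {seg.chrom}:{seg.start}-"
                f"{seg.end} extends beyond chromosome bounds [{lo}, {hi})"
            )


def _region_cin(
    segments: pd.DataFrame, start: int, end: int, t_gain: float, t_loss: float
) -> tuple[float, float]:
    """Gain and loss index of one region from one chromosome's segments."""
    length = end - start
    if length <= 0:
        raise ValidationError(f"region of non-positive length [{start}, {end})")
    if segments.empty:
        return 0.0, 0.0
    s = np.maximum(segments["start"].to_numpy(), start)
    e = np.minimum(segments["end"].to_numpy(), end)
    ov = np.maximum(0, e - s).astype(float)
    a = segments["log2_ratio"].to_numpy()
    gain = float(np.sum(np.where(a >= t_gain, a * ov, 0.0)) / length)
    loss = float(np.sum(np.where(a <= -t_loss, -a * ov, 0.0)) / length)
    return gain, loss


def cytoband_cin(
    profile: SegmentProfile,
    bands: CytobandMap,
    t_gain: float = 0.2,
    t_loss: float = 0.2,
) -> pd.DataFrame:
    """Per-cytoband CIN record for one sample.

    Returns a DataFrame indexed by band name with columns gain_index,
    loss_index, total_index.
    """
    if t_gain <= 0 or t_loss <= 0:
        raise ValueError("gain/loss thresholds must be positive")
    _validate_profile_against_map(profile, bands)
    by_chrom = {c: g for c, g in profile.segments.groupby("chrom", sort=False)}
    rows = []
    for band in bands.records.itertuples(index=False):
        segs = by_chrom.get(band.chrom, profile.segments.iloc[0:0])
        gain, loss = _region_cin(segs, band.start, band.end, t_gain, t_loss)
        rows.append((band.name, gain, loss, gain + loss))
    out = pd.DataFrame(rows, columns=["region", "gain_index", "loss_index", "total_index"])
    return out.set_index("region")


def chromosome_cin(
    profile: SegmentProfile,
    bands: CytobandMap,
    t_gain: float = 0.2,
    t_loss: float = 0.2,
) -> pd.DataFrame:
    """Whole-chromosome CIN record (region = span of the chromosome's bands)."""
    if t_gain <= 0 or t_loss <= 0:
        raise ValueError("gain/loss thresholds must be positive")
    _validate_profile_against_map(profile, bands)
    by_chrom = {c: g for c, g in profile.segments.groupby("chrom", sort=False)}
    rows = []
    for chrom, grp in bands.records.groupby("chrom", sort=False):
        start, end = int(grp["start"].min()), int(grp["end"].max())
        segs = by_chrom.get(chrom, profile.segments.iloc[0:0])
        gain, loss = _region_cin(segs, start, end, t_gain, t_loss)
        rows.append((str(chrom), gain, loss, gain + loss))
    out = pd.DataFrame(rows, columns=["region", "gain_index", "loss_index", "total_index"])
    return out.set_index("region")


def cin_matrix(
    profiles: list[SegmentProfile],
    bands: CytobandMap,
    t_gain: float = 0.2,
    t_loss: float = 0.2,
    level: str = "cytoband",
    channel: str = "total",
) -> FeatureMatrix:
    """CIN feature matrix (regions x samples) for the selection machinery."""
    if not profiles:
        raise ValueError("need at least one segment profile")
    if level not in ("cytoband", "chromosome"):
        raise ValueError(f"level must be cytoband|chromosome, got {level!r}")
    if channel not in ("total", "gain", "loss"):
        raise ValueError(f"channel must be total|gain|loss, got {channel!r}")
    fn = cytoband_cin if level == "cytoband" else chromosome_cin
    col = f"{channel}_index"
    cols = {}
    for p in profiles:
        if p.sample_id in cols:
            raise ValidationError(f"duplicate sample id {p.sample_id!r} in profiles")
        cols[p.sample_id] = fn(p, bands, t_gain, t_loss)[col]
    values = pd.DataFrame(cols)
    return FeatureMatrix("cin_cytoband", values)


def naive_segment(
    positions: np.ndarray,
    values: np.ndarray,
    chrom: str,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Fixed-window mean fallback segmenter for unsegmented probe data.

    A deliberately simple stand-in for a proper segmentation method:
    probes are bucketed into fixed genomic windows and each window becomes
    one segment at the window-mean log2 ratio. Use only when no segmented
    input is available.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    if positions.size == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "log2_ratio"])
    order = np.argsort(positions)
    positions, values = positions[order], values[order]
    bins = positions // window
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append((chrom, int(b * window), int((b + 1) * window),
                     float(values[sel].mean())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "log2_ratio"])
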