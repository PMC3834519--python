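"""Core in-memory containers shared by every pipeline stage.

All genomic intervals are stored 0-based, half-open. SEG files on disk are
interpreted as 1-based inclusive and converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

DATA_TYPES = (
    "gene",
    "mirna",
    "cin_cytoband",
    "serum_pos",
    "serum_neg",
    "urine_pos",
    "urine_neg",
    "combined",
)

RELAPSE = "relapse"
RELAPSE_FREE = "relapse_free"


class ValidationError(ValueError):
    """Raised when an input file or container violates its invariants."""


@dataclass
class FeatureMatrix:
    """One omics data type: real-valued features x samples.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns. NaN cells mark missing measurements; modelling stages require
    an imputed (finite) matrix.
    """

    data_type: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValidationError(
                f"unknown data_type {self.data_type!r}; expected one of {DATA_TYPES}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict(self, feature_ids) -> "FeatureMatrix":
        """Sub-matrix for the given features, preserving the given order."""
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return FeatureMatrix(self.data_type, self.values.loc[list(feature_ids)])


@dataclass
class CytobandMap:
    """Cytoband coordinates: (chrom, start, end, name), 0-based half-open.

    Within a chromosome, bands must be sorted and non-overlapping.
    """

    records: pd.DataFrame  # columns: chrom, start, end, name

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        required = ["chrom", "start", "end", "name"]
        if list(df.columns[:4]) != required:
            df = df.rename(
                columns=dict(zip(df.columns[:4], required))
            )
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"cytoband {bad['name']} has start >= end ({bad['start']} >= {bad['end']})"
            )
        if df["name"].duplicated().any():
            dups = df.loc[df["name"].duplicated(), "name"].tolist()
            raise ValidationError(f"duplicate cytoband names: {dups}")
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not (starts[1:] >= starts[:-1]).all():
                raise ValidationError(f"cytobands on {chrom} are not sorted by start")
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(f"overlapping cytobands on {chrom}")
        self.records = df

    @property
    def band_names(self) -> list[str]:
        return list(self.records["name"])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.records["chrom"]))

    def bands_on(self, chrom: str) -> pd.DataFrame:
        return self.records[self.records["chrom"] == chrom]

    def lookup(self, name: str) -> tuple[str, int, int]:
        row = self.records[self.records["name"] == name]
        if row.empty:
            raise KeyError(f"cytoband {name!r} not in map")
        r = row.iloc[0]
        return str(r["chrom"]), int(r["start"]), int(r["end"])


@dataclass
class SegmentProfile:
    """Piecewise-constant copy-number profile of one sample.

    ``segments`` columns: chrom, start, end, log2_ratio (0-based half-open;
    non-overlapping within a chromosome).
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.segments.reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"sample {self.sample_id}: segment with start >= end "
                f"({bad['chrom']}:{bad['start']}-{bad['end']})"
            )
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments on {chrom}"
                )
        self.segments = df


@dataclass
class AnnotatedVariantTable:
    """Multi-sample variants with gene/consequence/deleteriousness annotations.

    ``variants``: DataFrame with columns chrom, pos (1-based, VCF
    convention), ref, alt, gene, consequence, deleterious (bool), af
    (population allele frequency, NaN if unannotated).
    ``genotypes``: DataFrame (variants x samples) of alternate-allele
    counts: 0, 1, 2, or -1 for a missing call.
    """

    variants: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.variants) != len(self.genotypes):
            raise ValidationError(
                f"variant table ({len(self.variants)}) and genotype matrix "
                f"({len(self.genotypes)}) row counts differ"
            )
        if (self.variants["ref"] == self.variants["alt"]).any():
            raise ValidationError("variant with alt == ref")
        self.variants = self.variants.reset_index(drop=True)
        self.genotypes = self.genotypes.reset_index(drop=True).astype(np.int8)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, mask) -> "AnnotatedVariantTable":
        """Row-filtered copy (mask is boolean per variant)."""
        mask = np.asarray(mask, dtype=bool)
        return AnnotatedVariantTable(
            self.variants[mask].reset_index(drop=True),
            self.genotypes[mask].reset_index(drop=True),
        )

    def carrier_matrix(self) -> pd.DataFrame:
        """Boolean variants x samples matrix; missing calls are non-carriers."""
        return self.genotypes > 0


def check_labels(labels: Mapping[str, str], sample_ids) -> tuple[list[str], list[str]]:
    """Split sample ids into (relapse, relapse_free), validating coverage."""
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValidationError(f"samples without a label: {missing}")
    bad = {s: v for s, v in labels.items() if v not in (RELAPSE, RELAPSE_FREE)}
    if bad:
        raise ValidationError(f"labels must be '{RELAPSE}' or '{RELAPSE_FREE}': {bad}")
    rel = [s for s in sample_ids if labels[s] == RELAPSE]
    free = [s for s in sample_ids if labels[s] == RELAPSE_FREE]
    return rel, free


def labels_to_binary(labels: Mapping[str, str], sample_ids) -> np.ndarray:
    """0/1 vector over ``sample_ids`` (1 = relapse)."""
    rel, _ = check_labels(labels, sample_ids)
    rel_set = set(rel)
    return np.asarray([1 if s in rel_set else 0 for s in sample_ids], dtype=int)
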