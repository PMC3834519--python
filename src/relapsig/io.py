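"""Readers and writers for every on-disk format the pipeline touches.

Formats: TSV feature matrices (header = sample ids, first column = feature
id), SEG copy-number segments (1-based inclusive on disk, converted to
0-based half-open in memory), BED4 cytobands (0-based half-open), GMT gene
sets, 2-column label TSVs, and multi-sample VCF 4.2 with INFO keys GENE,
CSQ, DEL and AF (handled through pysam).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .containers import (
    AnnotatedVariantTable,
    CytobandMap,
    FeatureMatrix,
    SegmentProfile,
    ValidationError,
)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "seg_mean"]


# ---------------------------------------------------------------- matrices

def read_matrix(path, data_type: str) -> FeatureMatrix:
    """Read a features x samples TSV. Blank cells become NaN (missing)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValidationError(f"{path}:1: matrix header needs >=2 columns")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError(f"{path}:1: duplicate sample ids in header")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValidationError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                    f"expected {len(header)})"
                )
            ids.append(parts[0])
            try:
                rows.append(
                    [float(c) if c not in ("", "NA", "nan") else np.nan for c in parts[1:]]
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"{path}: duplicate feature id(s): {dups}")
    values = pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=float)
    return FeatureMatrix(data_type, values)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="")


def prepare_matrix(matrix: FeatureMatrix, max_missing_frac: float = 0.2) -> FeatureMatrix:
    """Drop features with too many missing cells, mean-impute the rest."""
    vals = matrix.values
    frac = vals.isna().mean(axis=1)
    drop = frac[frac > max_missing_frac].index
    if len(drop):
        warnings.warn(
            f"{matrix.data_type}: dropping {len(drop)} feature(s) with "
            f">{max_missing_frac:.0%} missing cells",
            stacklevel=2,
        )
        vals = vals.drop(index=drop)
    if vals.isna().any().any():
        vals = vals.apply(lambda r: r.fillna(r.mean()), axis=1)
    return FeatureMatrix(matrix.data_type, vals)


def normalize_metabolomics(matrix: FeatureMatrix) -> FeatureMatrix:
    """Raw LC-MS intensity normalization chain.

    Column total-intensity scaling (to the median sample total), then log2
    (with +1 offset), then per-feature z-score. Applies to raw, non-negative
    intensity matrices only.
    """
    vals = matrix.values
    if (vals < 0).any().any():
        raise ValidationError(
            f"{matrix.data_type}: negative intensities; normalization chain "
            "expects raw (non-negative) LC-MS intensities"
        )
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError(f"{matrix.data_type}: sample with zero total intensity")
    scaled = vals * (totals.median() / totals)
    logged = np.log2(scaled + 1.0)
    sd = logged.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = logged.sub(logged.mean(axis=1), axis=0).div(sd, axis=0)
    return FeatureMatrix(matrix.data_type, z)


# ---------------------------------------------------------------- segments

def read_segments(path) -> list[SegmentProfile]:
    """Read a SEG file (1-based inclusive) into 0-based half-open profiles."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: SEG file missing column(s) {missing}")
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        seg = pd.DataFrame(
            {
                "chrom": grp["chrom"].astype(str).to_numpy(),
                "start": grp["start"].astype(int).to_numpy() - 1,  # to 0-based
                "end": grp["end"].astype(int).to_numpy(),  # inclusive -> half-open
                "log2_ratio": grp["seg_mean"].astype(float).to_numpy(),
            }
        )
        profiles.append(SegmentProfile(str(sample), seg))
    return profiles


def write_segments(profiles: list[SegmentProfile], path) -> None:
    rows = []
    for p in profiles:
        for seg in p.segments.itertuples(index=False):
            rows.append(
                (p.sample_id, seg.chrom, int(seg.start) + 1, int(seg.end),
                 max(1, (int(seg.end) - int(seg.start)) // 10_000), seg.log2_ratio)
            )
    out = pd.DataFrame(rows, columns=SEG_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------- cytobands

def read_cytobands(path) -> CytobandMap:
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: BED4 needs 4 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from None
    return CytobandMap(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def write_cytobands(bands: CytobandMap, path) -> None:
    bands.records[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------- labels

def read_labels(path) -> dict[str, str]:
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: labels TSV needs 2 columns")
            if lineno == 1 and parts[1] not in ("relapse", "relapse_free"):
                continue  # header row
            if parts[0] in labels:
                raise ValidationError(f"{path}:{lineno}: duplicate sample {parts[0]!r}")
            labels[parts[0]] = parts[1]
    if not labels:
        raise ValidationError(f"{path}: no labels found")
    return labels


def write_labels(labels: Mapping[str, str], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tlabel\n")
        for s, v in labels.items():
            fh.write(f"{s}\t{v}\n")


# ---------------------------------------------------------------- gene sets

def read_gene_sets(path) -> dict[str, list[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return sets


# ---------------------------------------------------------------- variants

def read_variants(path, sample_ids=None) -> AnnotatedVariantTable:
    """Read an annotated multi-sample VCF (INFO keys GENE, CSQ, DEL, AF)."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in samples]
            if missing:
                raise ValidationError(f"{path}: VCF lacks samples {missing}")
            samples = list(sample_ids)
        recs, gts = [], []
        for rec in vf:
            info = rec.info
            for key in ("GENE", "CSQ", "DEL"):
                if key not in info:
                    raise ValidationError(
                        f"{path}: variant {rec.chrom}:{rec.pos} missing INFO key {key}"
                    )
            af = info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            recs.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else "N",
                    "gene": str(info["GENE"]),
                    "consequence": str(info["CSQ"]),
                    "deleterious": bool(int(info["DEL"])),
                    "af": float(af) if af is not None else np.nan,
                }
            )
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row.append(-1)
                else:
                    row.append(int(sum(1 for a in gt if a > 0)))
            gts.append(row)
    variants = pd.DataFrame(
        recs, columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                       "deleterious", "af"],
    )
    genotypes = pd.DataFrame(gts, columns=samples, dtype=np.int8)
    return AnnotatedVariantTable(variants, genotypes)


def write_variants(table: AnnotatedVariantTable, path, contig_lengths=None) -> None:
    """Write an AnnotatedVariantTable as uncompressed VCF 4.2."""
    header = pysam.VariantHeader()
    contigs = dict.fromkeys(table.variants["chrom"].astype(str))
    if contig_lengths is None:
        contig_lengths = {}
    for chrom in contigs:
        length = int(contig_lengths.get(chrom, int(table.variants.loc[
            table.variants["chrom"] == chrom, "pos"].max()) + 1_000))
        header.contigs.add(chrom, length=length)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ", 1, "String", "Consequence class")
    header.info.add("DEL", 1, "Integer", "Deleteriousness flag (1 = deleterious)")
    header.info.add("AF", "A", "Float", "Population allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in table.sample_ids:
        header.add_sample(s)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in table.variants.iterrows():
            rec = out.new_record(
                contig=str(v["chrom"]), start=int(v["pos"]) - 1,
                alleles=(str(v["ref"]), str(v["alt"])),
            )
            rec.info["GENE"] = str(v["gene"])
            rec.info["CSQ"] = str(v["consequence"])
            rec.info["DEL"] = int(bool(v["deleterious"]))
            if np.isfinite(v["af"]):
                rec.info["AF"] = float(v["af"])
            for s in table.sample_ids:
                rec.samples[s]["GT"] = gt_map[int(table.genotypes.at[i, s])]
            out.write(rec)
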