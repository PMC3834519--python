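"""Synthetic multi-omics cohort with planted relapse signal.

Emulates a 20 relapse / 20 relapse-free surgical cohort profiled across
six feature matrices (tumor gene expression, tumor miRNA expression and
four LC-MS biofluid matrices: serum/urine in positive/negative ESI mode),
per-sample copy-number segment profiles over a cytoband map, and an
annotated multi-sample VCF. Each data type carries a known set of planted
informative features so every downstream stage can be tested for
recovery; everything is reproducible from a single seed.

Generative model
----------------
* Expression/metabolite values are log2-scale Gaussian with per-feature
  SD 1. Informative features get a mean shift of ``effect_size`` SD units
  in the relapse group and are grouped into redundant blocks sharing a
  latent factor: x = sqrt(r)*f_block + sqrt(1-r)*e, giving within-block
  correlation r.
* Copy number: neutral log2 ratio 0 with segment-level noise SD 0.05;
  each altered cytoband receives one covering segment at the stated
  amplitude (gain positive, loss negative) in a ``penetrance`` fraction
  of relapse samples.
* Variants: signal genes carry rare deleterious protein-altering variants
  in relapse samples only (at ``carrier_rate_relapse`` per variant);
  background genes carry a mixture of consequence classes in both groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    AnnotatedVariantTable,
    CytobandMap,
    FeatureMatrix,
    RELAPSE,
    RELAPSE_FREE,
    SegmentProfile,
)
from . import io as rio


class SpecError(ValueError):
    """A SyntheticSpec field violates its constraints."""


@dataclass
class ExpressionSpec:
    """One log-scale feature matrix (expression or LC-MS metabolites).

    Three feature categories: ``n_informative`` independent planted
    features with a relapse-group mean shift of ``effect_size`` SD units;
    ``n_blocks`` redundant blocks of ``block_size`` features each sharing
    a latent factor (within-block correlation ``block_corr``) that itself
    carries an attenuated relapse shift of ``block_effect`` SD units —
    co-regulated partially informative modules the selection machinery
    should consecutively eliminate in favour of the planted features; and
    pure-noise features for the remainder.
    """

    n_features: int
    n_informative: int
    effect_size: float  # standardized mean shift (z units) in relapse group
    block_corr: float = 0.5  # within-block correlation of redundant features
    block_size: int = 4
    n_blocks: int = 3
    block_effect: Optional[float] = None  # default: effect_size / 2
    prefix: str = "F"

    def validate(self, name: str) -> None:
        if self.n_features < 1:
            raise SpecError(f"{name}.n_features must be >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise SpecError(f"{name}.n_informative must be in [0, n_features]")
        if not np.isfinite(self.effect_size):
            raise SpecError(f"{name}.effect_size must be finite")
        if not 0 <= self.block_corr < 1:
            raise SpecError(f"{name}.block_corr must be in [0, 1)")
        if self.block_size < 1:
            raise SpecError(f"{name}.block_size must be >= 1")
        if self.n_blocks < 0:
            raise SpecError(f"{name}.n_blocks must be >= 0")
        if self.n_informative + self.n_blocks * self.block_size > self.n_features:
            raise SpecError(
                f"{name}: informative + block features exceed n_features"
            )
        if self.block_effect is not None and not np.isfinite(self.block_effect):
            raise SpecError(f"{name}.block_effect must be finite")


@dataclass
class CnvSpec:
    """Copy-number design: cytoband map plus planted altered bands."""

    cytoband_map: Optional[CytobandMap] = None  # default map when None
    n_altered: int = 16
    amplitude: float = 0.6  # |log2 ratio| of altered-band segments
    penetrance: float = 0.8  # fraction of relapse samples carrying each alteration
    noise_sd: float = 0.05  # segment-level log2 noise
    altered_cytobands: Optional[list[tuple[str, str, float, float]]] = None
    # explicit (band, 'gain'|'loss', amplitude, penetrance) overrides sampling

    def validate(self) -> None:
        if self.altered_cytobands is not None:
            for band, direction, amp, pen in self.altered_cytobands:
                if direction not in ("gain", "loss"):
                    raise SpecError("cnv.altered_cytobands direction must be gain|loss")
                if not np.isfinite(amp):
                    raise SpecError("cnv.altered_cytobands amplitude must be finite")
                if not 0 < pen <= 1:
                    raise SpecError("cnv.altered_cytobands penetrance must be in (0,1]")
        else:
            if self.n_altered < 0:
                raise SpecError("cnv.n_altered must be >= 0")
            if not np.isfinite(self.amplitude) or self.amplitude <= 0:
                raise SpecError("cnv.amplitude must be finite and positive")
            if not 0 < self.penetrance <= 1:
                raise SpecError("cnv.penetrance must be in (0,1]")
        if self.noise_sd < 0:
            raise SpecError("cnv.noise_sd must be >= 0")


@dataclass
class VariantSpec:
    """Exome design: signal genes with relapse-only deleterious variants."""

    n_genes: int = 500
    n_signal_genes: int = 25
    carrier_rate_relapse: float = 0.3
    carrier_rate_free: float = 0.0  # 0 makes signal variants relapse-exclusive
    background_carrier_rate: float = 0.08

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SpecError("variants.n_genes must be >= 1")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            raise SpecError("variants.n_signal_genes must be in [0, n_genes]")
        if not 0 < self.carrier_rate_relapse <= 1:
            raise SpecError("variants.carrier_rate_relapse must be in (0,1]")
        if not 0 <= self.carrier_rate_free <= 1:
            raise SpecError("variants.carrier_rate_free must be in [0,1]")
        if not 0 <= self.background_carrier_rate <= 1:
            raise SpecError("variants.background_carrier_rate must be in [0,1]")


def _default_matrices() -> dict[str, ExpressionSpec]:
    return {
        "gene": ExpressionSpec(2000, 12, 2.0, 0.6, 4, 3, prefix="GENE"),
        "mirna": ExpressionSpec(800, 25, 1.5, 0.5, 5, 2, prefix="MIR"),
        "serum_pos": ExpressionSpec(1200, 14, 1.8, 0.5, 4, 2, prefix="SPOS_mz"),
        "serum_neg": ExpressionSpec(900, 10, 1.8, 0.5, 4, 2, prefix="SNEG_mz"),
        "urine_pos": ExpressionSpec(1000, 12, 1.5, 0.5, 4, 2, prefix="UPOS_mz"),
        "urine_neg": ExpressionSpec(900, 10, 1.5, 0.5, 4, 2, prefix="UNEG_mz"),
    }


@dataclass
class SyntheticSpec:
    """Full cohort design; ``seed`` fixes all randomness."""

    n_relapse: int = 20
    n_free: int = 20
    matrices: dict[str, ExpressionSpec] = field(default_factory=_default_matrices)
    cnv: CnvSpec = field(default_factory=CnvSpec)
    variants: VariantSpec = field(default_factory=VariantSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_relapse < 1:
            raise SpecError("n_relapse must be >= 1")
        if self.n_free < 1:
            raise SpecError("n_free must be >= 1")
        for name, m in self.matrices.items():
            m.validate(f"matrices[{name!r}]")
        self.cnv.validate()
        self.variants.validate()


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the planted ground truth."""

    labels: dict[str, str]
    matrices: dict[str, FeatureMatrix]
    segments: list[SegmentProfile]
    cytobands: CytobandMap
    variants: AnnotatedVariantTable
    truth: dict[str, list[str]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def validate(self) -> None:
        ids = set(self.labels)
        for dtype, m in self.matrices.items():
            if set(m.sample_ids) != ids:
                raise SpecError(f"matrix {dtype} sample set differs from labels")
        if {p.sample_id for p in self.segments} != ids:
            raise SpecError("segment profiles sample set differs from labels")
        if set(self.variants.sample_ids) != ids:
            raise SpecError("variant table sample set differs from labels")
        for dtype, planted in self.truth.items():
            if dtype in self.matrices:
                pool = set(self.matrices[dtype].feature_ids)
                if not set(planted) <= pool:
                    raise SpecError(f"truth[{dtype!r}] not a subset of feature ids")


def make_cytoband_map(n_chroms: int = 22, band_length: int = 4_000_000) -> CytobandMap:
    """Deterministic contiguous cytoband map for synthetic genomes.

    Chromosome ``c`` gets max(12, 40 - c) bands of equal length, named
    ``{c}p{i}``/``{c}q{i}`` for the two arms.
    """
    rows = []
    for c in range(1, n_chroms + 1):
        n_bands = max(12, 40 - c)
        half = n_bands // 2
        for i in range(n_bands):
            arm, k = ("p", half - i) if i < half else ("q", i - half + 1)
            rows.append(
                (str(c), i * band_length, (i + 1) * band_length, f"{c}{arm}{k}")
            )
    return CytobandMap(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def _gen_expression(
    spec: ExpressionSpec, y: np.ndarray, rng: np.random.Generator, data_type: str
) -> tuple[FeatureMatrix, list[str]]:
    n = len(y)
    ids = [f"{spec.prefix}{i:04d}" for i in range(1, spec.n_features + 1)]
    n_block_feats = spec.n_blocks * spec.block_size
    special = rng.choice(
        spec.n_features, size=spec.n_informative + n_block_feats, replace=False
    )
    informative = sorted(special[: spec.n_informative])
    block_members = special[spec.n_informative :]
    X = rng.normal(size=(spec.n_features, n))
    X[informative] += spec.effect_size * y  # shift relapse group
    r = spec.block_corr
    block_effect = (
        spec.effect_size / 2.0 if spec.block_effect is None else spec.block_effect
    )
    for b in range(spec.n_blocks):
        factor = rng.normal(size=n) + block_effect * y
        for j in block_members[b * spec.block_size : (b + 1) * spec.block_size]:
            X[j] = np.sqrt(r) * factor + np.sqrt(1 - r) * X[j]
    values = pd.DataFrame(
        X, index=ids, columns=[f"S{i:02d}" for i in range(1, n + 1)]
    )
    return FeatureMatrix(data_type, values), [ids[j] for j in informative]


def _gen_segments(
    cnv: CnvSpec,
    bands: CytobandMap,
    sample_ids: list[str],
    y: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[SegmentProfile], list[str]]:
    if cnv.altered_cytobands is not None:
        altered = list(cnv.altered_cytobands)
    else:
        names = bands.band_names
        picks = rng.choice(len(names), size=cnv.n_altered, replace=False)
        altered = [
            (names[j], "gain" if k % 2 == 0 else "loss", cnv.amplitude, cnv.penetrance)
            for k, j in enumerate(sorted(picks))
        ]
    # per altered band: which relapse samples carry it
    carrier_sets: dict[str, set[str]] = {}
    signed: dict[str, float] = {}
    for band, direction, amp, pen in altered:
        bands.lookup(band)  # raises if unknown
        hit = rng.random(len(sample_ids)) < pen
        carrier_sets[band] = {
            s for s, is_rel, h in zip(sample_ids, y == 1, hit) if is_rel and h
        }
        signed[band] = amp if direction == "gain" else -amp
    profiles = []
    for s in sample_ids:
        rows = []
        for chrom, grp in bands.records.groupby("chrom", sort=False):
            run_start = None
            for b in grp.itertuples(index=False):
                if b.name in carrier_sets and s in carrier_sets[b.name]:
                    if run_start is not None:
                        rows.append(
                            (chrom, run_start, b.start, rng.normal(0, cnv.noise_sd))
                        )
                        run_start = None
                    rows.append(
                        (chrom, b.start, b.end, signed[b.name] + rng.normal(0, cnv.noise_sd))
                    )
                elif run_start is None:
                    run_start = b.start
            if run_start is not None:
                rows.append(
                    (chrom, run_start, int(grp["end"].max()), rng.normal(0, cnv.noise_sd))
                )
        seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "log2_ratio"])
        profiles.append(SegmentProfile(s, seg))
    return profiles, [band for band, *_ in altered]


_BACKGROUND_CSQ = (
    ("missense_variant", 0.35),
    ("synonymous_variant", 0.25),
    ("intron_variant", 0.15),
    ("3_prime_UTR_variant", 0.15),
    ("stop_gained", 0.10),
)


def _gen_variants(
    vspec: VariantSpec,
    sample_ids: list[str],
    y: np.ndarray,
    n_chroms: int,
    rng: np.random.Generator,
) -> tuple[AnnotatedVariantTable, list[str]]:
    genes = [f"VG{i:04d}" for i in range(1, vspec.n_genes + 1)]
    signal = sorted(
        rng.choice(vspec.n_genes, size=vspec.n_signal_genes, replace=False)
    )
    signal_genes = {genes[j] for j in signal}
    rel_mask = y == 1
    free_mask = ~rel_mask
    recs, gts = [], []
    csq_names = [c for c, _ in _BACKGROUND_CSQ]
    csq_probs = np.array([p for _, p in _BACKGROUND_CSQ])
    for gi, gene in enumerate(genes):
        chrom = str(gi % n_chroms + 1)
        base_pos = 100_000 + (gi // n_chroms) * 50_000
        if gene in signal_genes:
            n_var = int(rng.integers(1, 4))
            for v in range(n_var):
                carriers = np.zeros(len(sample_ids), dtype=bool)
                carriers[rel_mask] = rng.random(rel_mask.sum()) < vspec.carrier_rate_relapse
                carriers[free_mask] = rng.random(free_mask.sum()) < vspec.carrier_rate_free
                af = float(rng.uniform(0.001, 0.02)) if rng.random() > 0.1 else np.nan
                recs.append(
                    (chrom, base_pos + v * 97 + 1, "A", "G", gene,
                     "missense_variant" if rng.random() < 0.8 else "stop_gained",
                     True, af)
                )
                gts.append(carriers.astype(np.int8))
        else:
            n_var = int(rng.integers(1, 3))
            for v in range(n_var):
                carriers = rng.random(len(sample_ids)) < vspec.background_carrier_rate
                csq = csq_names[int(rng.choice(len(csq_names), p=csq_probs))]
                dele = bool(rng.random() < 0.3) if csq in ("missense_variant",
                                                           "stop_gained") else False
                common = rng.random() < 0.5
                af = float(rng.uniform(0.05, 0.5)) if common else float(
                    rng.uniform(0.001, 0.04))
                recs.append((chrom, base_pos + v * 97 + 1, "C", "T", gene, csq, dele, af))
                gts.append(carriers.astype(np.int8))
    variants = pd.DataFrame(
        recs,
        columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                 "deleterious", "af"],
    )
    genotypes = pd.DataFrame(np.asarray(gts), columns=sample_ids)
    return AnnotatedVariantTable(variants, genotypes), sorted(signal_genes)


def generate_cohort(spec: SyntheticSpec) -> CohortBundle:
    """Generate the full cohort bundle; identical spec+seed is bit-identical."""
    spec.validate()
    n = spec.n_relapse + spec.n_free
    sample_ids = [f"S{i:02d}" for i in range(1, n + 1)]
    y = np.array([1] * spec.n_relapse + [0] * spec.n_free)
    labels = {
        s: (RELAPSE if yi == 1 else RELAPSE_FREE) for s, yi in zip(sample_ids, y)
    }
    master = np.random.SeedSequence(spec.seed)
    keys = list(spec.matrices) + ["cnv", "variants"]
    children = dict(zip(keys, master.spawn(len(keys))))

    matrices: dict[str, FeatureMatrix] = {}
    truth: dict[str, list[str]] = {}
    for dtype, mspec in spec.matrices.items():
        fm, planted = _gen_expression(
            mspec, y, np.random.default_rng(children[dtype]), dtype
        )
        fm.values.columns = sample_ids
        matrices[dtype] = fm
        truth[dtype] = planted

    bands = spec.cnv.cytoband_map or make_cytoband_map()
    segments, altered = _gen_segments(
        spec.cnv, bands, sample_ids, y, np.random.default_rng(children["cnv"])
    )
    truth["cin_cytoband"] = altered

    variants, signal_genes = _gen_variants(
        spec.variants, sample_ids, y, len(bands.chromosomes()),
        np.random.default_rng(children["variants"]),
    )
    truth["variant_genes"] = signal_genes

    bundle = CohortBundle(labels, matrices, segments, bands, variants, truth)
    bundle.validate()
    return bundle


def write_bundle(bundle: CohortBundle, directory) -> list[str]:
    """Serialise the bundle; returns the manifest of files written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []

    def _emit(name: str, writer, *args) -> None:
        path = directory / name
        try:
            writer(*args, path)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        manifest.append(name)

    for dtype, fm in bundle.matrices.items():
        _emit(f"{dtype}.tsv", rio.write_matrix, fm)
    _emit("segments.seg", rio.write_segments, bundle.segments)
    _emit("cytobands.bed", rio.write_cytobands, bundle.cytobands)
    _emit("variants.vcf", rio.write_variants, bundle.variants)
    _emit("labels.tsv", rio.write_labels, bundle.labels)
    truth_path = directory / "truth.json"
    try:
        truth_path.write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing {truth_path}: {exc}") from exc
    manifest.append("truth.json")
    return manifest


def read_bundle(directory) -> CohortBundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    directory = Path(directory)
    labels = rio.read_labels(directory / "labels.tsv")
    matrices = {}
    for dtype in ("gene", "mirna", "serum_pos", "serum_neg", "urine_pos", "urine_neg"):
        path = directory / f"{dtype}.tsv"
        if path.exists():
            matrices[dtype] = rio.read_matrix(path, dtype)
    segments = rio.read_segments(directory / "segments.seg")
    bands = rio.read_cytobands(directory / "cytobands.bed")
    variants = rio.read_variants(directory / "variants.vcf", list(labels))
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return CohortBundle(labels, matrices, segments, bands, variants, truth)


# counts emulate the study cohort's demographic table
_DEMOGRAPHICS = {
    "gender": [("Male", 22), ("Female", 18)],
    "tumor_grade": [("Grade 2", 33), ("Grade 3", 7)],
    "tumor_stage": [("I", 12), ("II", 24), ("IIA", 4)],
    "relapse": [("Yes", 20), ("No", 20)],
    "vital_status": [("Alive", 36), ("Dead", 4)],
    "age_group": [("<=40", 1), ("41-55", 3), ("56-70", 25), (">70", 11)],
}


def demo_clinical_table() -> pd.DataFrame:
    """40-sample clinical manifest mirroring the study cohort's demographics.

    Synthetic: category levels are assigned deterministically so that the
    per-level counts match the cohort description; joint distributions
    across columns are not modelled.
    """
    n = 40
    data: dict[str, list[str]] = {"sample": [f"S{i:02d}" for i in range(1, n + 1)]}
    for col, levels in _DEMOGRAPHICS.items():
        vals: list[str] = []
        for level, count in levels:
            vals.extend([level] * count)
        if len(vals) != n:
            raise AssertionError(f"demographic column {col} sums to {len(vals)}")
        data[col] = vals
    return pd.DataFrame(data)
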