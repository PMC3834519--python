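"""Relapse-exclusive deleterious-variant filtering and burden testing.

The variant cascade keeps non-synonymous, predicted-deleterious calls and
then restricts to variants carried only by relapse samples. Gene-level
burden collapses rare qualifying variants into a per-sample carrier
indicator and compares carrier counts between outcome groups with a
two-sided Fisher exact test; gene-set aggregation reports, per user gene
set, the affected genes/variants/samples plus a hypergeometric enrichment
p-value of the variant-bearing genes against the annotated background.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotatedVariantTable, check_labels

#: consequence classes treated as protein-altering
PROTEIN_ALTERING = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "inframe_insertion",
        "inframe_deletion",
    }
)


def filter_deleterious(table: AnnotatedVariantTable) -> AnnotatedVariantTable:
    """Keep protein-altering variants flagged deleterious."""
    for key in ("consequence", "deleterious"):
        if key not in table.variants.columns:
            raise KeyError(f"variant table missing annotation column {key!r}")
    csq = table.variants["consequence"].astype(str)
    mask = csq.isin(PROTEIN_ALTERING) & table.variants["deleterious"].astype(bool)
    return table.subset(mask.to_numpy())


def relapse_exclusive(
    table: AnnotatedVariantTable, labels: Mapping[str, str]
) -> AnnotatedVariantTable:
    """Keep variants with >=1 relapse carrier and zero relapse-free carriers.

    Missing genotypes count as non-carriers.
    """
    rel, free = check_labels(labels, table.sample_ids)
    carriers = table.carrier_matrix()
    mask = carriers[rel].any(axis=1) & ~carriers[free].any(axis=1)
    return table.subset(mask.to_numpy())


def _rare_mask(table: AnnotatedVariantTable, af_cutoff: float) -> np.ndarray:
    """Rare = annotated AF < cutoff, or no annotation and cohort AF < cutoff."""
    af = table.variants["af"].to_numpy(dtype=float)
    gt = table.genotypes.to_numpy()
    called = gt >= 0
    alt = np.where(called, gt, 0).sum(axis=1).astype(float)
    denom = 2.0 * called.sum(axis=1)
    cohort_af = np.divide(alt, denom, out=np.zeros_like(alt), where=denom > 0)
    return np.where(np.isfinite(af), af < af_cutoff, cohort_af < af_cutoff)


def gene_burden(
    table: AnnotatedVariantTable,
    labels: Mapping[str, str],
    af_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Collapsing burden test per gene.

    A sample is a carrier for a gene if it carries >=1 rare qualifying
    variant in it; carrier x group 2x2 tables are tested with a two-sided
    Fisher exact test. Returns one row per gene: carriers_relapse,
    carriers_free, n_variants, p — sorted by p then gene.
    """
    if not 0 < af_cutoff <= 1:
        raise ValueError("af_cutoff must be in (0, 1]")
    rel, free = check_labels(labels, table.sample_ids)
    rare = table.subset(_rare_mask(table, af_cutoff))
    carriers = rare.carrier_matrix()
    rows = []
    for gene, idx in rare.variants.groupby("gene", sort=True).groups.items():
        sub = carriers.loc[idx]
        carrier = sub.any(axis=0)
        a = int(carrier[rel].sum())
        b = int(carrier[free].sum())
        _, p = stats.fisher_exact(
            [[a, len(rel) - a], [b, len(free) - b]], alternative="two-sided"
        )
        rows.append((gene, a, b, len(idx), float(p)))
    out = pd.DataFrame(
        rows, columns=["gene", "carriers_relapse", "carriers_free", "n_variants", "p"]
    )
    return out.sort_values(["p", "gene"], ignore_index=True)


def set_aggregate(
    table: AnnotatedVariantTable,
    labels: Mapping[str, str],
    gene_sets: Mapping[str, list[str]],
    background: list[str] | None = None,
) -> pd.DataFrame:
    """Gene-set aggregation of qualifying variants.

    Per set: n_genes (set genes with >=1 qualifying variant), n_variants
    in those genes, n_cases / n_controls (relapse / relapse-free samples
    carrying >=1 qualifying variant in the set), and a one-sided
    hypergeometric enrichment p of variant-bearing genes in the set
    against the background gene universe (default: all genes annotated in
    the table).
    """
    rel, free = check_labels(labels, table.sample_ids)
    if background is None:
        background = sorted(set(table.variants["gene"]))
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    variant_genes = set(table.variants["gene"]) & bg
    carriers = table.carrier_matrix()
    rows = []
    for name, genes in gene_sets.items():
        genes_in_bg = set(genes) & bg
        hit_genes = sorted(genes_in_bg & variant_genes)
        in_set = table.variants["gene"].isin(hit_genes).to_numpy()
        n_variants = int(in_set.sum())
        if n_variants:
            any_carrier = carriers[in_set].any(axis=0)
            n_cases = int(any_carrier[rel].sum())
            n_controls = int(any_carrier[free].sum())
        else:
            n_cases = n_controls = 0
        # hypergeometric upper tail: >= observed overlap between the
        # set's background genes and the variant-bearing genes
        M, n, N, k = len(bg), len(variant_genes), len(genes_in_bg), len(hit_genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if N else 1.0
        rows.append((name, len(hit_genes), n_variants, n_cases, n_controls, p))
    out = pd.DataFrame(
        rows, columns=["set", "n_genes", "n_variants", "n_cases", "n_controls", "p"]
    )
    return out.sort_values(["p", "set"], ignore_index=True)
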