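"""End-to-end relapse-signature pipeline and run report.

Stages: per-type Welch prefilter -> SVM-RFE minimal panels -> LOO scoring
with bootstrap ROC -> CIN feature matrix from segments -> deleterious /
relapse-exclusive variant filtering with gene burden -> combined matrix ->
artificial-contrast random-forest ranking -> significance tiers ->
Kendall association network -> genomic coordinates. Every stage output is
written to a run directory as a plain file; the report contains only
numbers traceable to those files and is byte-reproducible for a fixed
seed and config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as rio
from .cin import cin_matrix
from .config import PipelineConfig
from .containers import ValidationError, labels_to_binary
from .evaluate import RocResult, roc_analysis
from .integrate import (
    RfAce,
    combine_panels,
    kendall_network,
    map_coordinates,
    select_top,
)
from .prefilter import filter_significant, welch_test
from .rfe import RfeResults, SvmRfe
from .synthetic import CohortBundle, SyntheticSpec, generate_cohort
from .variants import filter_deleterious, gene_burden, relapse_exclusive, set_aggregate

log = logging.getLogger("relapsig")


@dataclass
class RelapseSignatureResults:
    """Everything one pipeline run produced, plus the consolidated report."""

    report: dict
    rfe_results: dict[str, RfeResults]
    roc_results: dict[str, RocResult]
    ranked: Optional[pd.DataFrame]
    selection: Optional[dict]
    edges: Optional[pd.DataFrame]
    run_dir: Optional[Path]

    def summary(self) -> str:
        r = self.report
        lines = [
            "Relapse-signature pipeline",
            "=" * 60,
            f"samples: {r['n_samples']}  "
            f"({r['n_relapse']} relapse / {r['n_relapse_free']} relapse-free)",
            "",
            f"{'data type':<14}{'features':>9}{'prefiltered':>12}"
            f"{'panel':>7}{'LOO acc':>9}{'AUC':>7}  95% CI",
        ]
        for dtype, st in r["data_types"].items():
            ci = (
                f"[{st['auc_ci_low']:.3f}, {st['auc_ci_high']:.3f}]"
                if st.get("auc") is not None
                else "-"
            )
            lines.append(
                f"{dtype:<14}{st['n_features']:>9}{st['n_prefiltered']:>12}"
                f"{st.get('panel_size', 0):>7}"
                f"{st.get('loo_accuracy', float('nan')):>9.3f}"
                f"{st.get('auc', float('nan')):>7.3f}  {ci}"
            )
        v = r["variants"]
        lines += [
            "",
            f"variants: {v['n_total']} total, {v['n_deleterious']} deleterious "
            f"protein-altering, {v['n_relapse_exclusive']} relapse-exclusive "
            f"({v['n_relapse_exclusive_genes']} genes)",
        ]
        if self.selection is not None:
            comp = ", ".join(
                f"{k}: {v}" for k, v in sorted(self.selection["composition"].items())
            )
            lines += [
                f"integration: {len(self.ranked)} features ranked; "
                f"{len(self.selection['selected'])} selected at "
                f"p<={r['config']['p_select']:g} ({comp}); "
                f"{len(self.selection['top'])} in top tier",
                f"association network: {0 if self.edges is None else len(self.edges)} "
                f"edges",
            ]
        return "\n".join(lines)


class RelapseSignatureModel:
    """Fits the full multi-omics relapse-signature workflow to a cohort.

    Parameters
    ----------
    bundle : CohortBundle (from the synthetic generator or ``read_bundle``)
    config : PipelineConfig
    gene_sets : optional GMT-style mapping for variant set aggregation
    """

    def __init__(
        self,
        bundle: CohortBundle,
        config: Optional[PipelineConfig] = None,
        gene_sets: Optional[Mapping[str, list[str]]] = None,
    ):
        self.bundle = bundle
        self.config = config or PipelineConfig()
        self.gene_sets = gene_sets

    @classmethod
    def from_directory(cls, directory, config=None, gene_sets=None):
        from .synthetic import read_bundle

        return cls(read_bundle(directory), config, gene_sets)

    @classmethod
    def from_spec(cls, spec: SyntheticSpec, config=None, gene_sets=None):
        return cls(generate_cohort(spec), config, gene_sets)

    # ------------------------------------------------------------------ fit

    def fit(self, run_dir=None) -> RelapseSignatureResults:
        t0 = time.monotonic()
        cfg = self.config
        bundle = self.bundle
        run_dir = Path(run_dir) if run_dir is not None else None
        if run_dir is not None:
            run_dir.mkdir(parents=True, exist_ok=True)
            cfg.to_yaml(run_dir / "config.yaml")
        labels = bundle.labels
        sample_ids = bundle.sample_ids
        y = labels_to_binary(labels, sample_ids)

        seeds = np.random.SeedSequence(cfg.seed)
        stage_names = [
            "cin", *sorted(bundle.matrices), "cin_cytoband", "ace", "boot",
        ]
        stage_seed = {
            name: int(ss.generate_state(1)[0] % (2**31))
            for name, ss in zip(stage_names, seeds.spawn(len(stage_names)))
        }

        matrices = dict(bundle.matrices)
        matrices["cin_cytoband"] = cin_matrix(
            bundle.segments,
            bundle.cytobands,
            cfg.cin_t_gain,
            cfg.cin_t_loss,
            cfg.cin_level,
            cfg.cin_channel,
        )
        if run_dir is not None:
            rio.write_matrix(matrices["cin_cytoband"], run_dir / "cin_matrix.tsv")

        report: dict = {
            "n_samples": len(sample_ids),
            "n_relapse": int(y.sum()),
            "n_relapse_free": int(len(y) - y.sum()),
            "config": cfg.to_dict(),
            "data_types": {},
        }
        rfe_results: dict[str, RfeResults] = {}
        roc_results: dict[str, RocResult] = {}
        panels: dict[str, list[str]] = {}

        for dtype in list(bundle.matrices) + ["cin_cytoband"]:
            fm = rio.prepare_matrix(matrices[dtype], cfg.missing_max_frac)
            stats_tbl = welch_test(fm, labels)
            shortlist = filter_significant(
                stats_tbl, cfg.alpha_for(dtype), bh=cfg.bh_correct
            )
            st = {
                "n_features": fm.shape[0],
                "n_prefiltered": len(shortlist),
            }
            log.info(
                "seed=%d type=%s prefilter %d -> %d",
                cfg.seed, dtype, fm.shape[0], len(shortlist),
            )
            if run_dir is not None:
                out = stats_tbl.copy()
                out["pass"] = (
                    out.index.isin(shortlist).astype(int)
                )
                out.index.name = "feature"
                out.to_csv(run_dir / f"prefilter_{dtype}.tsv", sep="\t",
                           float_format="%.6g")
            if shortlist:
                model = SvmRfe(fm.restrict(shortlist), labels, cfg)
                res = model.fit(seed=stage_seed[dtype])
                rfe_results[dtype] = res
                panels[dtype] = res.selected_panel
                scores, loo_acc = model.loo_validate(res.selected_panel)
                roc = roc_analysis(
                    scores.to_numpy(), y, cfg.boot_reps, cfg.ci_level,
                    seed=stage_seed["boot"] + hash_offset(dtype),
                )
                roc_results[dtype] = roc
                st.update(
                    panel_size=res.selected_k,
                    panel=res.selected_panel,
                    cv_accuracy=float(
                        res.accuracy_curve.set_index("k").loc[
                            res.selected_k, "mean_accuracy"
                        ]
                    ),
                    loo_accuracy=loo_acc,
                    auc=roc.auc,
                    auc_ci_low=roc.ci_low,
                    auc_ci_high=roc.ci_high,
                )
                if run_dir is not None:
                    res.accuracy_curve.to_csv(
                        run_dir / f"curve_{dtype}.tsv", sep="\t", index=False,
                        float_format="%.6g",
                    )
                    pd.Series(res.selected_panel, name="feature").to_csv(
                        run_dir / f"panel_{dtype}.tsv", sep="\t", index=False
                    )
                    pd.Series(res.elimination_order, name="feature").to_csv(
                        run_dir / f"elimination_{dtype}.tsv", sep="\t", index=False
                    )
                    scores.rename_axis("sample").to_csv(
                        run_dir / f"loo_{dtype}.tsv", sep="\t", float_format="%.6g"
                    )
                    roc.points.to_csv(
                        run_dir / f"roc_{dtype}.tsv", sep="\t", index=False,
                        float_format="%.6g",
                    )
            else:
                panels[dtype] = []
            report["data_types"][dtype] = st

        # ------------------------------------------------------- variants
        vt = bundle.variants
        deleterious = filter_deleterious(vt)
        exclusive = relapse_exclusive(deleterious, labels)
        burden = gene_burden(deleterious, labels, cfg.burden_af_cutoff)
        report["variants"] = {
            "n_total": vt.n_variants,
            "n_deleterious": deleterious.n_variants,
            "n_relapse_exclusive": exclusive.n_variants,
            "n_relapse_exclusive_genes": int(exclusive.variants["gene"].nunique()),
            "burden_top_genes": burden.head(10)["gene"].tolist(),
        }
        if run_dir is not None:
            rio.write_variants(exclusive, run_dir / "variants_relapse_exclusive.vcf")
            burden.to_csv(run_dir / "burden.tsv", sep="\t", index=False,
                          float_format="%.6g")
        if self.gene_sets:
            agg = set_aggregate(exclusive, labels, self.gene_sets)
            report["variants"]["set_aggregation"] = agg.to_dict("records")
            if run_dir is not None:
                agg.to_csv(run_dir / "set_aggregation.tsv", sep="\t", index=False,
                           float_format="%.6g")

        # ------------------------------------------------------ integrate
        ranked = selection = edges = None
        nonempty = {d: p for d, p in panels.items() if p}
        if sum(len(p) for p in nonempty.values()) >= 2:
            prepared = {
                d: rio.prepare_matrix(matrices[d], cfg.missing_max_frac)
                for d in nonempty
            }
            combined = combine_panels(nonempty, prepared)
            ace = RfAce(combined, labels, cfg)
            ace_res = ace.fit(seed=stage_seed["ace"])
            ranked = ace_res.ranked
            selection = select_top(ranked, cfg.p_select, cfg.p_top)
            report["integration"] = {
                "n_combined": combined.shape[0],
                "n_selected": len(selection["selected"]),
                "n_top": len(selection["top"]),
                "composition": selection["composition"],
            }
            if len(selection["selected"]) >= 2:
                edges = kendall_network(
                    combined.restrict(selection["selected"]), cfg.edge_alpha
                )
                report["integration"]["n_edges"] = len(edges)
            coords = map_coordinates(
                ranked[["feature", "data_type"]], bands=bundle.cytobands
            )
            if run_dir is not None:
                rio.write_matrix(combined, run_dir / "combined.tsv")
                ranked.to_csv(run_dir / "ranked.tsv", sep="\t", index=False,
                              float_format="%.6g")
                coords.to_csv(run_dir / "coordinates.tsv", sep="\t", index=False)
                if edges is not None:
                    edges.to_csv(run_dir / "edges.tsv", sep="\t", index=False,
                                 float_format="%.6g")

        elapsed = time.monotonic() - t0
        log.info("seed=%d pipeline finished in %.1fs", cfg.seed, elapsed)
        if run_dir is not None:
            (run_dir / "report.json").write_text(
                json.dumps(report, indent=1, sort_keys=True, default=_jsonable)
            )
            (run_dir / "run.log").write_text(
                f"seed={cfg.seed} wall_clock_s={elapsed:.2f}\n"
            )
        return RelapseSignatureResults(
            report, rfe_results, roc_results, ranked, selection, edges, run_dir
        )


def hash_offset(name: str) -> int:
    """Small deterministic per-stage offset (stable across processes)."""
    return sum(ord(c) * (i + 1) for i, c in enumerate(name)) % 10_007


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(
    config: Optional[PipelineConfig] = None,
    inputs=None,
    spec: Optional[SyntheticSpec] = None,
    run_dir=None,
    gene_sets=None,
) -> RelapseSignatureResults:
    """One-call pipeline over an input directory or a synthetic spec."""
    if (inputs is None) == (spec is None):
        raise ValueError("provide exactly one of inputs directory or synthetic spec")
    if inputs is not None:
        model = RelapseSignatureModel.from_directory(inputs, config, gene_sets)
    else:
        model = RelapseSignatureModel.from_spec(spec, config, gene_sets)
    return model.fit(run_dir=run_dir)


def cohort_summary(
    labels: Mapping[str, str],
    clinical: pd.DataFrame,
    rollups: Optional[Mapping[str, Mapping[str, list[str]]]] = None,
) -> dict[str, pd.DataFrame]:
    """Counts and percentages per categorical clinical column.

    Percentages are 100*count/total rounded to one decimal. ``rollups``
    maps a column name to named groups of levels that are additionally
    reported as combined rows (e.g. grouping tumor stages).
    """
    if "sample" not in clinical.columns:
        raise ValidationError("clinical table needs a 'sample' column")
    unknown = [s for s in clinical["sample"] if s not in labels]
    if unknown:
        raise ValidationError(f"clinical table has unknown sample(s): {unknown}")
    total = len(clinical)
    out: dict[str, pd.DataFrame] = {}
    for col in clinical.columns:
        if col == "sample":
            continue
        counts = clinical[col].value_counts()
        levels = list(dict.fromkeys(clinical[col]))
        rows = [
            (lvl, int(counts.get(lvl, 0)), round(100.0 * counts.get(lvl, 0) / total, 1))
            for lvl in levels
        ]
        if rollups and col in rollups:
            for name, group in rollups[col].items():
                c = int(sum(counts.get(lvl, 0) for lvl in group))
                rows.append((name, c, round(100.0 * c / total, 1)))
        out[col] = pd.DataFrame(rows, columns=["level", "count", "pct"])
    return out
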