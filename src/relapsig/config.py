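"""Run configuration with documented defaults.

Every tunable threshold of the pipeline lives here so a run can be
reproduced from its config echo plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All pipeline thresholds and resampling sizes.

    Parameters
    ----------
    alpha_prefilter : per-feature Welch-test significance threshold used to
        shortlist features before SVM-RFE. The workflow uses raw p-values
        (no multiple-testing correction) by default; set ``bh_correct`` to
        apply Benjamini-Hochberg instead.
    alpha_by_type : optional per-data-type override of ``alpha_prefilter``.
    svm_c : soft-margin cost of the linear SVM.
    rfe_step : features removed per RFE iteration (1 = classic RFE).
    mc_reps : Monte-Carlo 2-fold cross-validation repetitions per panel
        size; each repetition contributes two accuracy values (each half
        serves once as the test set). The reference procedure used 10,000;
        the accuracy-curve shape is robust to far fewer.
    boot_reps : bootstrap resamples for the ROC AUC confidence interval.
    ci_level : confidence level for the AUC interval.
    cin_t_gain, cin_t_loss : log2-ratio thresholds above/below which a
        segment counts as gained/lost (0.2 ~ one copy at ~50% purity).
    cin_level / cin_channel : resolution (cytoband|chromosome) and channel
        (total|gain|loss) of the CIN feature matrix.
    burden_af_cutoff : population-AF cutoff below which a variant is
        "rare" for the gene-level burden test; cohort allele frequency is
        the fallback when the annotation is absent.
    ace_forests, ace_trees : repetitions and trees per forest for the
        artificial-contrast random-forest ranking.
    ace_contrast_quantile : contrast-importance quantile each real feature
        must beat.
    p_select, p_top : integration p-value thresholds for the selected set
        and the (very stringent) top tier. p_top defaults to 1e-30 for
        fidelity with the reference workflow; on desk-scale cohorts a
        practical value such as 1e-6 is recommended.
    edge_alpha : significance threshold for Kendall association edges.
    missing_max_frac : features with a larger fraction of missing cells
        are dropped at load time; the rest are mean-imputed.
    seed : master seed; fixes every source of randomness.
    """

    alpha_prefilter: float = 0.05
    alpha_by_type: dict = field(default_factory=dict)
    bh_correct: bool = False
    svm_c: float = 1.0
    rfe_step: int = 1
    mc_reps: int = 200
    boot_reps: int = 2000
    ci_level: float = 0.95
    cin_t_gain: float = 0.2
    cin_t_loss: float = 0.2
    cin_level: str = "cytoband"
    cin_channel: str = "total"
    burden_af_cutoff: float = 0.05
    ace_forests: int = 20
    ace_trees: int = 100
    ace_contrast_quantile: float = 0.75
    p_select: float = 0.01
    p_top: float = 1e-30
    edge_alpha: float = 0.01
    missing_max_frac: float = 0.2
    n_threads: int = 1  # worker threads for forest growing; never affects results
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "alpha_prefilter": 0 < self.alpha_prefilter <= 1,
            "svm_c": self.svm_c > 0,
            "rfe_step": self.rfe_step >= 1,
            "mc_reps": 1 <= self.mc_reps <= 10_000,
            "boot_reps": self.boot_reps >= 100,
            "ci_level": 0 < self.ci_level < 1,
            "cin_t_gain": self.cin_t_gain > 0,
            "cin_t_loss": self.cin_t_loss > 0,
            "cin_level": self.cin_level in ("cytoband", "chromosome"),
            "cin_channel": self.cin_channel in ("total", "gain", "loss"),
            "burden_af_cutoff": 0 < self.burden_af_cutoff <= 1,
            "ace_forests": self.ace_forests >= 2,
            "ace_trees": self.ace_trees >= 10,
            "ace_contrast_quantile": 0 < self.ace_contrast_quantile < 1,
            "p_select": 0 < self.p_select <= 1,
            "p_top": 0 < self.p_top <= 1,
            "edge_alpha": 0 < self.edge_alpha <= 1,
            "missing_max_frac": 0 <= self.missing_max_frac < 1,
            "n_threads": self.n_threads >= 1,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid config value(s) for: {', '.join(bad)}")

    def alpha_for(self, data_type: str) -> float:
        return float(self.alpha_by_type.get(data_type, self.alpha_prefilter))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
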