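# Methods

`relapsig` implements a multi-omics relapse-signature workflow for a
two-arm surgical cohort: patients who relapsed within long-term follow-up
versus patients cured by surgery. Six feature-by-sample matrices (tumor
gene expression, tumor miRNA expression, and serum/urine LC-MS metabolite
intensities in positive and negative ESI mode), per-sample copy-number
segment profiles, and an annotated multi-sample VCF are reduced to a
ranked multi-omics signature in five stages. This note records the models,
the defaults and their rationale, the numerical conventions, and what the
synthetic cohort does and does not establish.

## Stage 1 — significance prefiltering

Each feature is tested with a two-sided Welch (unequal-variance) t-test
between the relapse and relapse-free groups; features at p <= alpha
(default 0.05, per-data-type override available) form the shortlist.
Raw p-values are used by default because the workflow treats the filter
as a coarse screen ahead of the wrapper selection, not as an inference
step; Benjamini-Hochberg adjustment is available behind `bh_correct`.
The Welch statistic is computed from the explicit closed form

    t = (x̄₁ − x̄₂) / sqrt(s₁²/n₁ + s₂²/n₂),

with Welch–Satterthwaite degrees of freedom, so that an independent
reference implementation can serve as an oracle in the tests. Degenerate
inputs are given conventions rather than NaNs: both groups constant with
equal means → t = 0, p = 1; constant with different means → t = ±inf,
p = 0; fewer than two non-missing values in a group → untestable, the
feature is excluded from all downstream selection.

## Stage 2 — SVM-RFE minimal panels

Features are ranked by recursive feature elimination around a linear
soft-margin SVM (cost C = 1 by default; the linear kernel is required
because the ranking criterion is the squared weight w_i²). The classic
recipe — train, rank by w_i², drop the worst, repeat — produces the
elimination ranking. Ties in the criterion are broken toward removing the
lexicographically smallest feature id, which makes the ranking fully
deterministic.

The accuracy-vs-panel-size curve is estimated by Monte-Carlo 2-fold
cross-validation: each repetition draws one stratified random halving of
the cohort, and both halves serve once as the test set (stratification
guards against single-class halves at n = 40). Crucially, the curve is
**nested**: the elimination is re-run from scratch inside every training
half, and each surviving set is scored on the held-out half. An earlier
design scored the surviving sets of a single cohort-level elimination
path, but those survivors are cherry-picked on the very samples being
cross-validated, and with a strong planted signal the curve saturates at
exactly 1.0 by k ≈ 5 — the panel-size choice then collapses to whatever
tiny k first touches the ceiling and the curve carries no information
about generalization. The nested curve is an (approximately) unbiased
estimate of the accuracy of a size-k panel selected on independent data,
which is the quantity the panel-size rule needs.

The selected panel size k\* is the smallest k attaining the maximum of
the mean-accuracy curve ("maximal accuracy with the minimal number of
top-ranked features"), and the reported panel is the top k\* of the
cohort-level elimination ranking. The panel is then validated by
leave-one-out cross-validation: each sample is scored by an SVM trained
on the other n−1 (standardization always uses training-fold statistics
only; the tests include an explicit no-leakage check).

The default number of CV repetitions is 200 (each contributing two
accuracy values). The reference procedure used 10,000 permutations; the
curve's argmax is stable far below that, and 200 keeps a full seven-type
run near a minute. `mc_reps` is a config knob up to 10,000.

For speed, the SVM is trained through scikit-learn's low-level libsvm
binding (the identical C-SVC solver behind `SVC`, without per-call
estimator overhead — about 35× faster at n = 40); the test suite asserts
equality of weights and bias with `SVC` to 1e-8 on random instances, and
the code falls back to `SVC` automatically if the private binding is
unavailable.

## Stage 3 — ROC evaluation

LOO decision scores yield the ROC curve and the tie-aware trapezoidal
AUC (equivalently Mann-Whitney with half credit for ties). The 95%
confidence interval is a stratified percentile bootstrap (default 2000
resamples): samples are resampled with replacement within each outcome
arm, so every resample keeps the 20/20 design and a one-class resample is
impossible. A DeLong asymptotic interval is available as an alternative
(`method="delong"`). In a 400-dataset null simulation at n = 20+20 the
percentile interval covers AUC = 0.5 about 94% of the time — slightly
below nominal, a known small-sample property of bootstrap intervals for
rank statistics.

## Stage 4a — chromosomal instability (CIN) index

The published analyses cite an external definition for the CIN index
without reproducing it, so the package fixes its own definition and all
tests target it: for a region B of length L (a cytoband, or the span of a
chromosome's bands),

    gain(B) = Σ_{segments s: a_s ≥ t_gain}  a_s  · |s ∩ B| / L
    loss(B) = Σ_{segments s: a_s ≤ −t_loss} |a_s| · |s ∩ B| / L
    total(B) = gain(B) + loss(B),

an amplitude-weighted, length-normalized burden of calls beyond the
thresholds (defaults ±0.2 log2, roughly a single-copy change at ~50%
tumor purity). Unsegmented bases contribute nothing. Whether the original
study weighted by amplitude or used a binary altered fraction is not
recoverable; this choice is therefore a documented package definition,
verified exactly (1e-12) against a per-base brute-force oracle. The
per-sample cytoband indices form a feature matrix that enters stages 1–3
like any expression matrix. Input log2 ratios are assumed already
normalized against matched non-tumor tissue. SEG files are read as
1-based inclusive and converted to the internal 0-based half-open
convention. A deliberately naive fixed-window mean segmenter is included
only for unsegmented probe input and is not a substitute for a proper
segmentation method.

## Stage 4b — variant cascade and burden

The variant cascade keeps calls that are (i) protein-altering (missense,
stop gained/lost, start lost, frameshift, splice donor/acceptor, inframe
indel) **and** flagged deleterious, then (ii) carried by at least one
relapse sample and by no relapse-free sample (missing genotypes count as
non-carriers). Both steps are row filters, so they commute — a property
the tests assert. The gene-level burden test collapses rare qualifying
variants (annotated population AF < 0.05 by default; cohort allele
frequency is the fallback when the annotation is missing) into a
per-sample carrier indicator and applies a two-sided Fisher exact test
(point-probability method) to the carrier × outcome 2×2 table.
Knowledgebase-driven pathway content is replaced by user-supplied GMT
gene sets: per set the package reports affected genes, variants, and
case/control carrier counts (the control count is structurally zero after
the relapse-exclusive filter) plus a one-sided hypergeometric enrichment
p of variant-bearing genes against the annotated background.

## Stage 5 — integration

The per-type panels are row-bound into one combined matrix (feature ids
namespaced `type:id`, rows z-scored). Ranking uses a random forest with
artificial contrasts: in each of F = 20 forest repetitions the matrix is
augmented with an independently permuted copy of every feature, a
100-tree forest is grown (mtry = ceil(sqrt(p)) over the real feature
count, unlimited depth), and out-of-bag permutation importance is
recorded for every real feature and every contrast. Contrasts are
marginally identical to their sources but carry no label information, so
their importance distribution is an empirical null. Each real feature is
compared across repetitions against the 0.75-quantile of that
repetition's contrast importances with a one-sided paired t-test; its
normalized score is its mean importance divided by the mean contrast
quantile (clipped at zero). The published method's exact normalization
and testing machinery are not recoverable from an archival source; this
contrast-quantile scheme is the package's documented re-design, not a
re-implementation. A per-tree shortcut makes the OOB permutation exact
and fast: permuting a feature a tree never splits on cannot change that
tree's predictions, so only the tree's own features are scored.

Two nested significance tiers are reported: the selected set at
p ≤ 0.01 and a top tier at p ≤ 1e-30 for fidelity with the reference
workflow. A paired t-test over 20 repetitions cannot reach 1e-30 on
desk-scale data, so the top tier is empty under the defaults; a practical
`p_top` (e.g. 1e-6) should be configured for real use. Selected features
are linked by Kendall tau-b (tie-corrected) association edges at
p ≤ 0.01 — exact null enumeration below n = 10, normal approximation
otherwise — and mapped to genomic coordinates where a locus annotation
exists (metabolite features are unmapped by design).

## Synthetic cohort

The generator emulates the study design — 20 relapse / 20 relapse-free —
with planted, known signal so every stage is testable without patient
data. No per-type variance or effect structure is published; the defaults
below are stated assumptions chosen once for realism, not estimates.

- **Expression/metabolites**: log2-scale Gaussian, per-feature SD 1.
  Planted informative features are independent with a relapse-group mean
  shift of `effect_size` SD units (gene 2000 features / 12 informative at
  effect 2.0; miRNA 800/25 at 1.5; serum 1200/14 and 900/10 at 1.8;
  urine 1000/12 and 900/10 at 1.5). Separate redundant blocks (3 blocks
  of 4 for genes; 2 blocks elsewhere) share a latent factor with
  within-block correlation 0.5–0.6 whose factor carries an attenuated
  (half-effect) relapse shift — co-regulated, partially informative
  modules the selection machinery should discard in favour of the planted
  features. The remainder is i.i.d. noise. Effect 2.0 at n = 20+20 gives
  per-feature Welch power ≈ 1 at alpha 0.05, and the expected shortlist
  sizes (≈ 110–140 per type) match the scale of the study's post-filter
  feature counts.
- **Copy number**: a deterministic contiguous synthetic cytoband map (22
  chromosomes, 627 bands of 4 Mb); neutral segments at log2 0 with
  segment-level noise SD 0.05; 16 altered cytobands (alternating
  gain/loss, amplitude ±0.6) each receiving one covering segment in a
  penetrance-0.8 fraction of relapse samples.
- **Variants**: 500 genes; 25 signal genes carry rare deleterious
  protein-altering variants in relapse samples only (carrier rate 0.3 per
  variant; the relapse-free carrier rate defaults to 0, making the signal
  relapse-exclusive by construction); background genes carry a mixture of
  consequence classes in both arms (carrier rate 0.08) with a
  common/rare AF mixture.

Everything is driven by one seed through independently spawned
sub-streams, and identical spec + seed reproduces byte-identical
serialized bundles. What passing tests on this cohort show is that the
machinery recovers planted signal of the stated strength and stays
calibrated under the null; they do not show that real relapse signatures
are as strong, that real features are Gaussian or independent, or that
batch effects, confounding and annotation error — all absent from the
generator — would not dominate a real cohort. The synthetic metabolite
matrices are generated on the already-normalized log scale; the raw-
intensity normalization chain (column total-intensity scaling → log2 →
per-feature z-score, a documented stand-in for an under-specified
published order) is applied only when the loader is told intensities are
raw.

## Reported demographics

`demo_clinical_table()` reconstructs the study cohort's categorical
demographic counts (gender, grade, stage, vital status, age bins) as a
40-row synthetic manifest with the correct per-level counts but no joint
structure across columns; `cohort_summary` reproduces the percentage
table from it exactly (percentage = 100·count/total, one decimal), with
named roll-ups for grouped levels such as the combined stage II group.

## Numerical conventions and problem sizes

- Genomic intervals are 0-based half-open internally; SEG input/output is
  1-based inclusive; BED is native 0-based.
- Matrix cells may be missing on input; features with > 20% missing cells
  are dropped with a warning, the rest are mean-imputed per feature
  before modeling.
- Classification at a decision score of exactly zero predicts the
  relapse-free class.
- The test suite and the acceptance script run the planted-signal
  recovery at the full study conditions (2000 genes, seeds 1–5, 200 CV
  repetitions) and scale only the auxiliary end-to-end reruns (the
  byte-identity check uses a 150-gene cohort), sizes chosen so a complete
  run stays near a minute per stage on one core.

## Known limitations

- The percentile bootstrap slightly under-covers at n = 40 (≈ 94% for a
  nominal 95%); DeLong is available when calibration matters.
- The artificial-contrast test controls the rate of flagged features
  under a fresh-data null at about the nominal level, but within a single
  cohort it will flag features whose in-sample association is genuinely
  strong by chance; at n = 40 roughly 2–3% of pure-noise features are
  flagged at p ≤ 0.01.
- The greedy RFE ranking is not optimal under strong feature correlation;
  redundant co-regulated features are eliminated in an order that depends
  on sampling noise.
- No purity/ploidy correction, no allele-specific copy number, no
  tumor/normal subtraction: segment ratios and somatic status are trusted
  from input.
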