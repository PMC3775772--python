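# Methods

## Stability statistics

For a gene with per-sample RPKM values x₁…xₙ (n ≥ 2):

* mean RPKM x̄;
* CV% = 100 · s / x̄ with the sample (n−1) standard deviation s. The
  denominator convention is not universal; at the cohort sizes this
  statistic is meant for (tens to thousands of samples) the n vs n−1
  difference is far below the reporting precision. It is switchable via
  the `ddof` argument. A gene whose values are all identical gets CV
  exactly 0 (the variance computation is bypassed to avoid summation
  round-off).
* MFC = max / min, flagged infinite exactly when the minimum is 0. An
  infinite MFC can never pass a finite MFC criterion, which is the
  intended behaviour: a gene silent in even one sample is useless as a
  control.

Both statistics are invariant under multiplying all values by a positive
scalar; the test suite asserts this exactly, along with agreement with
brute-force oracles on hundreds of random instances.

Genes with all-zero expression raise an error rather than being silently
dropped: expression matrices are expected to be pre-filtered to detected
genes, and silent data loss inside a statistics routine is worse than a
loud failure.

## Ranking, panels, quantile curves

Stability tables rank genes by ascending CV with ties broken
lexicographically by gene id, making the ranking a deterministic function
of the matrix. Panel summaries use the plain median (middle value, or
mean of the two central values at even panel size) and min/max ranges.

The transcriptome-context curves sort genes by mean RPKM and compute CV
quantiles (default levels 5, 25, 50, 75%) in a rolling window (default
2000 ranked genes, step 1). Quantiles use linear interpolation between
order statistics; each window is summarised at the mean RPKM of its
central gene. `quantile_position` classifies a gene at the smallest level
whose curve value at the nearest window is ≥ the gene's CV — the
non-strict comparison is deliberate, so a gene sitting exactly on a
window's median classifies at the 50% level rather than the 75%. Genes
whose mean falls outside the curve support are classified against the
nearest window, with a warning.

## Selection and cross-dataset scoring

Selection keeps genes with CV < 25% and finite MFC < 5 (strict
inequalities: boundary genes are excluded), stratified by mean
expression: high = mean > 100 RPKM, mid = 25 < mean ≤ 100. Genes at or
below 25 RPKM are never selected — too little template for a reliable
qPCR denominator. The thresholds are parameters (`SelectionCriteria`);
the defaults are the screen's published operating point.

Cross-dataset scoring counts the CV criterion and the MFC criterion as
*separate* per-dataset passes and halves the total. This is the only
reading consistent with half-integer scores: a gene passing CV everywhere
but MFC in only half the cohorts scores 7.5 out of 10. A gene missing
from a dataset simply earns no passes there (with a warning) rather than
failing the whole run. Ties in the score ranking break by ascending mean
CV across datasets, then gene id.

The published screen's final shortlisting step — manually promoting or
demoting genes between strata based on their behaviour in other cohorts —
is a curation judgment and is intentionally not automated; the automatic
selector reports the strata as computed.

## GeNorm M

Relative quantities from Ct values use q = E^(Ct_min − Ct) per gene
(default efficiency E = 2, perfect doubling, since per-assay efficiencies
are rarely available; a per-gene Series is accepted). Pairwise variation
V(j,k) is the (n−1) standard deviation of log2(q_j/q_k) across samples;
M(j) is the mean of V(j,k) over all partners k ≠ j, computed on the full
panel. Log base 2 throughout. A stepwise mode repeatedly removes the
highest-M gene (ties: the lexicographically larger id) down to a final
pair. M is exactly invariant to per-gene and per-sample rescaling, so the
choice of quantity units cannot affect the ranking.

## ddCt validation statistics

RQ = 2^(−ddCt) holds to machine precision by construction. The
calibrator dCt is the mean over the calibrator samples (a single
calibrator reduces to its own dCt). RQ spread statistics (CV%, MFC) are
computed over the non-calibrator samples by default — the calibrator's
RQ is identically 1 and would only dilute the spread — switchable via
`include_calibrator`.

Spearman correlation uses average ranks for ties (scipy's convention,
cross-checked in the tests against a hand rank-averaging oracle). Under
the synthetic noise-free Ct model with an exactly constant control,
dCt is an affine decreasing function of log2 RPKM of the target, so
ρ(RPKM, dCt) = −1 exactly; the tests assert this identity.

## Synthetic studies

The generator emulates the statistical shape of multi-cohort bulk RNA-seq
RPKM matrices, not their biology:

* per-gene mean RPKM drawn log-uniformly over `mean_log2_range`
  (default 2..12 in log2, i.e. 4–4096 RPKM, covering the range where
  published per-gene summaries place both control-gene panels);
* per-gene CV targets: planted stable genes at `stable_cv_target`
  (default 10%), background genes uniform over `variable_cv_range`
  (default 40–120%) — the observed spread of ordinary genes in cancer
  cohorts;
* per-sample values log-normal with σ = sqrt(ln(1 + CV²)) and
  μ = ln(mean) − σ²/2, so the population mean and CV are exactly the
  targets. A CV target of 0 degenerates to an exactly constant gene.
* Ct tables via Ct = intercept − slope·log2(RPKM) + N(0, noise_sd):
  intercept 30 (Ct at 1 RPKM), slope 1 cycle per doubling (ideal
  chemistry), noise 0.25 cycles (typical technical replicate scatter).

Defaults describe a 10-cohort study of 2000 genes × 100 samples with 5%
planted stable genes. A log-normal law on RPKM was chosen over a count
model (negative binomial + length normalisation) because the statistics
under test operate on RPKM directly; simulating reads would add machinery
without changing what the tests can show. The generator deliberately has
**no** batch effects, library-size artifacts, gene-length bias or
correlation structure between genes — cohorts differ only by independent
sampling. Consequently, passing tests demonstrate that the statistics,
selection logic and scoring behave correctly and recover planted signal;
they do not demonstrate robustness to the systematic biases of real
cohorts.

Reproducibility: a master seed spawns independent substreams via numpy
`SeedSequence` entropy lists — `[seed, 0]` for the gene universe,
`[seed, 1+d]` for dataset d, and a label-keyed stream for Ct noise — so
regenerating with more datasets never perturbs earlier ones, and repeated
calls are bit-identical. The planted class labels live in a sidecar table
(`gene_universe` / `labels.tsv`), never in the expression files, so
downstream code cannot read the answers.

## Validation-contrast design

The control-gene-choice experiment pairs each replicate's statistics
under a stable (10% CV) and a variable (80% CV) control. The correlation
contrast uses a *variable* target gene (the realistic use case: a marker
gene whose expression genuinely differs between samples), while the RQ
spread contrast uses a *consistent* target gene — that is how each
validation is run in practice, and a consistent target makes the RQ
spread attributable to the control alone. Panels of 15 samples mirror a
typical qPCR validation plate.

## Pipeline

`run_screen` ingests datasets, computes per-dataset and pooled stability
tables, selects stratified candidates in the **first** configured dataset
(the discovery cohort — screen in one cohort, score in all), scores them
across every dataset, computes quantile curves on the pooled matrix and
writes everything as TSV plus a JSON manifest (inputs, parameters,
version, seed) sufficient to reproduce the run bit for bit. Cohort
combination takes the gene-id intersection and namespaces sample ids as
`label:sample` — complete rows, no imputation, no silent collisions.
Pooled statistics are computed on the concatenated sample matrix, not by
averaging per-cohort statistics.

## Known limitations

* RPKM matrices are accepted as given; no cross-cohort renormalisation is
  attempted, so cohorts quantified with different pipelines pool at face
  value.
* The GeNorm V(n/n+1) analysis for choosing how many controls to combine
  is not implemented (out of scope; single-control normalisation only).
* Efficiency-corrected ddCt (per-assay amplification efficiencies in the
  RQ formula) is not implemented; efficiencies enter only the GeNorm
  quantity transform.
* The synthetic generator's independence assumptions (above) bound what
  the planted-recovery results say about real data.
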