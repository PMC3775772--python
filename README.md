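# ctrlgenes

Screening and validation of maximally consistent endogenous control genes
from multi-cohort RNA-seq expression matrices.

## The problem

Relative quantification by qRT-PCR (the ddCt method: dCt = Ct<sub>target</sub> −
Ct<sub>control</sub>, ddCt = dCt<sub>sample</sub> − dCt<sub>calibrator</sub>, RQ = 2<sup>−ddCt</sup>)
normalises every measurement against an endogenous control gene that is
assumed constant across samples. In practice the conventional controls
(GAPDH, ACTB, TBP, ...) vary substantially between patient samples —
especially in cancer — and every bit of that variation propagates directly
into the reported RQ values. RNA-seq cohorts of hundreds to thousands of
samples make it possible to *measure* expression consistency
transcriptome-wide and pick controls empirically.

`ctrlgenes` implements that screen for anyone choosing normalisation genes
for qPCR panels, MRD assays or expression studies:

* **Stability statistics** per gene across the samples of a cohort, from
  RPKM matrices: the coefficient of variation `CV% = 100 · s / x̄` (sample
  standard deviation over mean) and the maximum fold change
  `MFC = max / min` (infinite when any sample reads zero). Both are scale
  invariant, so they compare genes across expression levels and cohorts.
* **Stratified selection**: candidates with `CV < 25%` and `MFC < 5`,
  reported separately for highly (mean RPKM > 100) and moderately
  (25 < mean ≤ 100) expressed genes.
* **Cross-dataset scoring**: in each of *D* cohorts a gene earns one pass
  for the CV criterion and one for the MFC criterion;
  `score = passes / 2 ∈ [0, D]`, so a universally consistent gene scores
  *D* and half-integers flag genes passing only one criterion somewhere.
* **Transcriptome context**: CV quantile curves (5/25/50/75%) over rolling
  windows of 2000 expression-ranked genes, and classification of a gene's
  CV against them.
* **qPCR validation**: GeNorm M values (mean SD of pairwise log2
  expression ratios; lower = more consistent), Spearman correlation
  between RPKM and dCt, and CV/MFC of RQ values under different controls.
* **A synthetic-study generator** with planted stable genes (log-normal
  per-gene law with dispersion solved from the target CV via
  `CV² = exp(σ²) − 1`) and matched Ct tables from a log-linear
  amplification model, so the whole pipeline is testable end to end.

Three published per-gene stability panels ship with the package (19
conventional controls, 12 microarray-derived candidates, 40 top screen
candidates, each with mean RPKM, CV% and MFC in a 55-sample leukemia
cohort and/or a pooled 1933-sample pan-cancer cohort) — see
`ctrlgenes.datasets`.

## Worked example

```python
import ctrlgenes as cg
from ctrlgenes.datasets import load_conventional_controls, as_stability_table

# how variable are the 19 conventional controls in the leukemia cohort?
panel = load_conventional_controls()
table = as_stability_table(panel, "leucegene")
s = cg.panel_summary(table, panel["gene"])
print(f"median CV = {s.median_cv:.1f}%  (range {s.cv_range[0]:.1f}-{s.cv_range[1]:.1f})")
print(f"median MFC = {s.median_mfc:.1f}  (range {s.mfc_range[0]:.1f}-{s.mfc_range[1]:.1f})")

# screen a synthetic 10-dataset study (2000 genes x 100 samples each,
# 5% planted stable genes at 10% CV) and score candidates across cohorts
cfg = cg.SyntheticConfig(seed=1)
study = cg.generate_study(cfg)
tables = [cg.stability_table(m) for m in study]
crit = cg.SelectionCriteria()                     # CV<25%, MFC<5
high = cg.select_candidates(tables[0], crit, "high")
mid = cg.select_candidates(tables[0], crit, "mid")
print(f"candidates: {len(high)} high-stratum, {len(mid)} mid-stratum")
genes = list(high["gene"]) + list(mid["gene"])
card = cg.score_across_datasets(tables, crit, genes)
print(card[["rank", "gene", "mean_cv", "score"]].head(5).to_string(index=False))
```

prints

```
median CV = 42.6%  (range 22.8-69.1)
median MFC = 8.3  (range 2.5-31.7)
candidates: 52 high-stratum, 19 mid-stratum
 rank   gene  mean_cv  score
    1 G01963 9.475241   10.0
    2 G01207 9.496522   10.0
    3 G01808 9.556443   10.0
    4 G01888 9.617457   10.0
    5 G01437 9.619208   10.0
```

The conventional panel's median CV of 42.6% (and up to 31.7-fold
expression swings) is why convention is a poor way to pick a control. In
the synthetic screen the top of the scorecard — genes passing both
criteria in all 10 cohorts, score 10.0 — is occupied by the planted
stable genes (mean CV near the 10% target).

## Command line

```
ctrlgenes simulate --outdir study/               # synthetic study + labels
ctrlgenes screen run_config.json                 # full screen -> TSVs + manifest
ctrlgenes score m1.tsv m2.tsv --genes HNRNPL,TBP # cross-dataset scoring
ctrlgenes genorm ct.tsv                          # GeNorm M values
ctrlgenes rq ct.tsv --target CD33 --control HNRNPL --calibrator CB1
ctrlgenes correlate rpkm.tsv ct.tsv --target CD33 --controls HNRNPL,GAPDH
```

Exit codes: 0 success, 2 input error, 3 internal error. Matrix files are
gene × sample TSV/CSV (`--dialect`, `--decimal-mark comma` for
decimal-comma files).

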