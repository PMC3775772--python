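"""Built-in reference tables: published per-gene stability statistics.

Three small panels ship with the package, transcribed from the published
summary statistics (decimal-comma TSVs, as printed):

* ``conventional_controls`` — 19 housekeeping genes in common qPCR use
  (TBP, GAPDH, ACTB, ...), with mean RPKM, CV% and MFC in both a
  55-sample leukemia cohort ("leucegene") and a pooled 1933-sample
  pan-cancer cohort ("tcga").
* ``microarray_candidates`` — 12 genes proposed as stable from microarray
  meta-analysis (mostly ribosomal proteins plus SRP14 and OAZ1), same
  columns.
* ``leucegene_candidates`` — the 40 top-ranked candidate control genes
  from the leukemia transcriptome screen (CV<25%, MFC<5), split into the
  high (mean > 100 RPKM) and mid (25-100 RPKM) expression strata.

These are per-gene summary statistics, not expression matrices: they feed
panel summaries and selection examples, and acceptance checks that the
package reproduces the published panel medians from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("ctrlgenes.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t", decimal=",")


def load_conventional_controls() -> pd.DataFrame:
    """19 conventional qPCR control genes with published CV%/MFC."""
    return _load("conventional_controls.tsv")


def load_microarray_candidates() -> pd.DataFrame:
    """12 microarray-derived candidate control genes with published CV%/MFC."""
    return _load("microarray_candidates.tsv")


def load_leucegene_candidates() -> pd.DataFrame:
    """40 leukemia-screen candidates with published stratum, mean, CV%, MFC."""
    return _load("leucegene_candidates.tsv")


def as_stability_table(panel: pd.DataFrame, cohort: str | None = None) -> pd.DataFrame:
    """Reshape a published panel into the stability-table layout.

    ``cohort`` selects the ``<cohort>_mean/cv/mfc`` column triple for the
    two-cohort panels ('leucegene' or 'tcga'); the single-cohort candidate
    panel uses its plain ``mean/cv/mfc`` columns. Ranks are recomputed by
    ascending CV, ties broken by gene id.
    """
    if cohort is not None:
        cols = {f"{cohort}_mean": "mean_rpkm", f"{cohort}_cv": "cv_percent",
                f"{cohort}_mfc": "mfc"}
    else:
        cols = {"mean": "mean_rpkm", "cv": "cv_percent", "mfc": "mfc"}
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise KeyError(f"panel lacks columns {missing}")
    df = panel[["gene", *cols]].rename(columns=cols)
    df = df.sort_values(["cv_percent", "gene"], kind="mergesort").reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df
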