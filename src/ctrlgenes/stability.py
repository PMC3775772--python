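"""Per-gene expression-stability statistics and transcriptome-wide context.

The two stability statistics used throughout the screen are

* CV% — coefficient of variation: sample standard deviation divided by the
  mean RPKM, as a percentage. The primary ranking statistic.
* MFC — maximum fold change: maximum divided by minimum RPKM across
  samples. Sensitive to single outlier samples; infinite when any sample
  has zero expression, which automatically disqualifies the gene from any
  finite MFC criterion.

Both are invariant under multiplying all expression values by a positive
scalar, so they compare genes across expression levels and cohorts.

:func:`quantile_curves` places individual genes in transcriptome context:
genes are ranked by mean expression and CV quantiles are computed over a
rolling window of ranked genes, giving "how variable is a typical gene at
this expression level" curves against which a candidate's CV can be
classified (:func:`quantile_position`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

DEFAULT_WINDOW = 2000
DEFAULT_LEVELS = (5.0, 25.0, 50.0, 75.0)


@dataclass(frozen=True)
class StabilityRecord:
    gene_id: str
    mean_rpkm: float
    cv_percent: float
    mfc: float  # math.inf when the minimum RPKM is 0

    @property
    def mfc_is_infinite(self) -> bool:
        return math.isinf(self.mfc)


@dataclass(frozen=True)
class PanelSummary:
    """Median and range of CV% and MFC over a named gene panel."""

    genes: tuple[str, ...]
    median_cv: float
    cv_range: tuple[float, float]
    median_mfc: float
    mfc_range: tuple[float, float]


@dataclass
class QuantileCurves:
    """CV quantile curves over rolling windows of expression-ranked genes."""

    window_size: int
    quantile_levels: tuple[float, ...]
    # one row per window: center mean RPKM + one CV column per level
    table: pd.DataFrame


def gene_stability(values, gene_id: str = "", ddof: int = 1) -> StabilityRecord:
    """Stability statistics for a single gene's per-sample RPKM vector.

    Parameters
    ----------
    values:
        Per-sample RPKM values, all >= 0; at least two samples.
    ddof:
        Delta degrees of freedom for the standard deviation. The default 1
        (sample sd) is conventional; at cohort sizes in the tens to
        thousands of samples the choice is numerically irrelevant.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"gene {gene_id!r}: need >=2 samples, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError(f"gene {gene_id!r}: non-finite expression value")
    if (arr < 0).any():
        raise ValueError(f"gene {gene_id!r}: negative expression value")
    mean = float(arr.mean())
    if mean == 0.0:
        raise ValueError(f"gene {gene_id!r}: all-zero expression, CV undefined")
    mn, mx = float(arr.min()), float(arr.max())
    # a constant gene has zero variance by definition; bypass summation
    # round-off in the variance
    cv = 0.0 if mn == mx else float(arr.std(ddof=ddof) / mean * 100.0)
    mfc = math.inf if mn == 0.0 else mx / mn
    return StabilityRecord(gene_id, mean, cv, mfc)


def stability_table(matrix: ExpressionMatrix, ddof: int = 1) -> pd.DataFrame:
    """Per-gene stability statistics for a whole dataset, ranked by CV.

    Returns a DataFrame with columns ``gene``, ``mean_rpkm``,
    ``cv_percent``, ``mfc`` and ``rank`` (1 = lowest CV), sorted by rank.
    CV ties are broken by gene id, so the ranking is a deterministic
    function of the matrix. The dataset label is kept in
    ``df.attrs["dataset_label"]``.
    """
    vals = matrix.data.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("need >=2 samples to compute stability statistics")
    means = vals.mean(axis=1)
    if (means == 0).any():
        gene = matrix.data.index[np.flatnonzero(means == 0)[0]]
        raise ValueError(f"gene {gene!r}: all-zero expression, CV undefined")
    mins = vals.min(axis=1)
    maxs = vals.max(axis=1)
    cvs = np.where(
        mins == maxs, 0.0, vals.std(axis=1, ddof=ddof) / means * 100.0
    )
    with np.errstate(divide="ignore"):
        mfcs = np.where(mins == 0.0, np.inf, maxs / np.where(mins == 0, 1, mins))
    df = pd.DataFrame(
        {
            "gene": matrix.data.index.astype(str),
            "mean_rpkm": means,
            "cv_percent": cvs,
            "mfc": mfcs,
        }
    )
    df = df.sort_values(["cv_percent", "gene"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["dataset_label"] = matrix.label
    return df


def panel_summary(table: pd.DataFrame, genes) -> PanelSummary:
    """Median and range of CV%/MFC over a panel of genes in one dataset.

    The median is the middle value for odd panel size and the mean of the
    two central values for even size (plain median).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene panel")
    sub = table.set_index("gene")
    missing = [g for g in genes if g not in sub.index]
    if missing:
        raise KeyError(f"panel genes absent from table: {missing}")
    cv = sub.loc[genes, "cv_percent"].to_numpy(dtype=float)
    mfc = sub.loc[genes, "mfc"].to_numpy(dtype=float)
    return PanelSummary(
        genes=tuple(genes),
        median_cv=float(np.median(cv)),
        cv_range=(float(cv.min()), float(cv.max())),
        median_mfc=float(np.median(mfc)),
        mfc_range=(float(mfc.min()), float(mfc.max())),
    )


def quantile_curves(
    matrix: ExpressionMatrix,
    window: int = DEFAULT_WINDOW,
    levels=DEFAULT_LEVELS,
    step: int = 1,
    ddof: int = 1,
) -> QuantileCurves:
    """CV quantiles over rolling windows of genes ranked by mean RPKM.

    Genes are sorted ascending by mean expression; for each window of
    ``window`` consecutive ranked genes (advanced by ``step`` genes, fully
    rolling by default) the requested quantiles of CV% within the window
    are recorded, along with the mean RPKM of the window's central gene.
    """
    levels = tuple(float(q) for q in levels)
    if any(not 0 <= q <= 100 for q in levels):
        raise ValueError("quantile levels must lie in [0, 100]")
    if sorted(levels) != list(levels):
        raise ValueError("quantile levels must be increasing")
    table = stability_table(matrix, ddof=ddof)
    n = len(table)
    if window < 2 or window > n:
        raise ValueError(f"window size {window} invalid for {n} genes")
    if step < 1:
        raise ValueError("step must be >= 1")
    by_mean = table.sort_values(["mean_rpkm", "gene"], kind="mergesort")
    means = by_mean["mean_rpkm"].to_numpy()
    cvs = by_mean["cv_percent"].to_numpy()
    starts = np.arange(0, n - window + 1, step)
    centers = means[starts + window // 2]
    rows = np.empty((len(starts), len(levels)))
    for i, s in enumerate(starts):
        rows[i] = np.percentile(cvs[s : s + window], levels)
    out = pd.DataFrame(rows, columns=[f"q{q:g}" for q in levels])
    out.insert(0, "center_mean_rpkm", centers)
    return QuantileCurves(window_size=window, quantile_levels=levels, table=out)


def quantile_position(
    gene_id: str, curves: QuantileCurves, table: pd.DataFrame
) -> float | None:
    """Classify a gene's CV against the transcriptome quantile curves.

    Looks up the window whose center mean RPKM is nearest the gene's mean
    (nearest-window extrapolation outside the curve support) and returns
    the smallest quantile level whose curve CV there is >= the gene's CV,
    or None if the gene lies above every curve.
    """
    sub = table.set_index("gene")
    if gene_id not in sub.index:
        raise KeyError(f"gene {gene_id!r} not in stability table")
    mean = float(sub.loc[gene_id, "mean_rpkm"])
    cv = float(sub.loc[gene_id, "cv_percent"])
    centers = curves.table["center_mean_rpkm"].to_numpy()
    if mean < centers.min() or mean > centers.max():
        warnings.warn(
            f"gene {gene_id!r} mean RPKM {mean:g} outside curve support; "
            "using nearest window"
        )
    idx = int(np.argmin(np.abs(centers - mean)))
    for q in curves.quantile_levels:
        if cv <= float(curves.table.iloc[idx][f"q{q:g}"]):
            return q
    return None


def write_stability_table(table: pd.DataFrame, path) -> None:
    """Export as TSV with columns (rank, gene, mean, cv_percent, mfc)."""
    out = table[["rank", "gene", "mean_rpkm", "cv_percent", "mfc"]]
    out.to_csv(path, sep="\t", index=False)


def write_quantile_curves(curves: QuantileCurves, path) -> None:
    curves.table.to_csv(path, sep="\t", index=False)
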