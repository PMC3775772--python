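"""Stratified candidate selection and cross-dataset criterion scoring.

Candidates are genes whose expression is both tight (CV% below a cutoff)
and free of outliers (finite MFC below a cutoff), selected separately in
two mean-expression strata so that moderately and highly expressed
candidates are reported side by side: high (mean RPKM > 100) and mid
(25 < mean RPKM <= 100). Genes with mean <= 25 RPKM are considered too
weakly expressed to serve as qPCR controls and are never selected.

Cross-dataset scoring generalises the selection to many cohorts: in each
dataset a gene earns one pass for CV < cv_max and one for MFC < mfc_max;
the score is the total number of passes divided by two, so a gene meeting
both criteria in all of 10 datasets scores 10.0 and half-integer scores
mark genes passing only one criterion somewhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for the stability screen; inequalities are strict."""

    cv_max: float = 25.0
    mfc_max: float = 5.0
    stratum_bounds: tuple[float, float] = (25.0, 100.0)  # (low, mid) RPKM

    def __post_init__(self) -> None:
        if not self.cv_max > 0:
            raise ValueError("cv_max must be positive")
        if not self.mfc_max >= 1:
            raise ValueError("mfc_max must be >= 1")
        low, mid = self.stratum_bounds
        if not low < mid:
            raise ValueError("stratum bounds must satisfy low < mid")


@dataclass(frozen=True)
class RecoveryMetrics:
    """Precision/recall of planted-stable genes among the top-scored."""

    top_k: int
    n_planted: int
    true_positives: int
    precision: float
    recall: float


def _stratum_mask(means: pd.Series, criteria: SelectionCriteria, stratum: str):
    low, mid = criteria.stratum_bounds
    if stratum == "high":
        return means > mid
    if stratum == "mid":
        return (means > low) & (means <= mid)
    raise ValueError(f"stratum must be 'high' or 'mid', got {stratum!r}")


def select_candidates(
    table: pd.DataFrame, criteria: SelectionCriteria, stratum: str
) -> pd.DataFrame:
    """Candidate control genes in one expression stratum of one dataset.

    Keeps genes with ``cv_percent < cv_max`` and finite ``mfc < mfc_max``
    whose mean RPKM falls in the requested stratum, ordered by ascending
    CV. An empty result is valid.
    """
    passing = (
        (table["cv_percent"] < criteria.cv_max)
        & np.isfinite(table["mfc"])
        & (table["mfc"] < criteria.mfc_max)
        & _stratum_mask(table["mean_rpkm"], criteria, stratum)
    )
    out = table.loc[passing].sort_values(
        ["cv_percent", "gene"], kind="mergesort"
    )
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_across_datasets(
    tables: list[pd.DataFrame], criteria: SelectionCriteria, genes
) -> pd.DataFrame:
    """Score candidate genes by criterion passes across many datasets.

    Each dataset contributes one pass flag for CV < cv_max and one for
    finite MFC < mfc_max; ``score = passes / 2``. A gene missing from a
    dataset contributes no passes there (with a warning). The returned
    DataFrame carries per-dataset boolean columns ``cv_pass:<label>`` and
    ``mfc_pass:<label>``, the score, and a rank ordered by descending
    score with ties broken by ascending mean CV across datasets, then by
    gene id.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    if not tables:
        raise ValueError("need at least one stability table")
    rows: dict[str, dict] = {g: {} for g in genes}
    cv_sums = {g: [] for g in genes}
    for i, table in enumerate(tables):
        label = table.attrs.get("dataset_label") or f"dataset{i}"
        sub = table.set_index("gene")
        for g in genes:
            if g not in sub.index:
                warnings.warn(f"gene {g!r} missing from dataset {label!r}")
                cv_pass = mfc_pass = False
            else:
                rec = sub.loc[g]
                cv_pass = bool(rec["cv_percent"] < criteria.cv_max)
                mfc_pass = bool(
                    math.isfinite(rec["mfc"]) and rec["mfc"] < criteria.mfc_max
                )
                cv_sums[g].append(float(rec["cv_percent"]))
            rows[g][f"cv_pass:{label}"] = cv_pass
            rows[g][f"mfc_pass:{label}"] = mfc_pass
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    flag_cols = list(df.columns)
    df["n_passes"] = df[flag_cols].sum(axis=1).astype(int)
    df["score"] = df["n_passes"] / 2.0
    df["mean_cv"] = [
        float(np.mean(cv_sums[g])) if cv_sums[g] else np.nan for g in df.index
    ]
    df = df.reset_index()
    df = df.sort_values(
        ["score", "mean_cv", "gene"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def recover_planted(
    scorecard: pd.DataFrame, labels: pd.DataFrame, top_k: int
) -> RecoveryMetrics:
    """Precision/recall of planted-stable genes among the top-k scored.

    ``labels`` is the synthetic generator's sidecar table with columns
    ``gene_id`` and ``class`` ('stable' / 'variable').
    """
    if top_k > len(scorecard):
        raise ValueError(f"top_k={top_k} exceeds {len(scorecard)} scored genes")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    lab = labels.set_index("gene_id")["class"]
    missing = scorecard.loc[~scorecard["gene"].isin(lab.index), "gene"]
    if len(missing):
        raise KeyError(f"labels missing for genes: {list(missing)[:5]}")
    top = scorecard.nsmallest(top_k, "rank")["gene"]
    n_planted = int((lab.loc[scorecard["gene"]] == "stable").sum())
    tp = int((lab.loc[top] == "stable").sum())
    return RecoveryMetrics(
        top_k=top_k,
        n_planted=n_planted,
        true_positives=tp,
        precision=tp / top_k,
        recall=tp / n_planted if n_planted else float("nan"),
    )


def write_scorecard(scorecard: pd.DataFrame, path) -> None:
    """Export the scorecard as TSV (rank, gene, mean_cv, score, flags)."""
    lead = ["rank", "gene", "mean_cv", "score", "n_passes"]
    cols = lead + [c for c in scorecard.columns if c not in lead]
    scorecard[cols].to_csv(path, sep="\t", index=False)
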