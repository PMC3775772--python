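"""ddCt relative quantification and RNA-seq/qPCR concordance statistics.

The ddCt method expresses a target gene's qPCR signal relative to a
control gene and a calibrator sample:

    dCt  = Ct(target) - Ct(control)          (per sample)
    ddCt = dCt(sample) - dCt(calibrator)
    RQ   = 2^(-ddCt)

so RQ = 1 for the calibrator itself and doubles for every cycle of extra
target template relative to the control. Because dCt subtracts the
control's Ct, any instability of the control gene propagates directly
into every RQ — which is precisely what the stability screen is meant to
prevent, and what the validation statistics here quantify:

* :func:`correlation_validation` — Spearman correlation between a target
  gene's RPKM (RNA-seq) and its dCt (qPCR) across samples. With a perfect
  assay and a truly constant control this is exactly -1 (more transcript,
  lower dCt); a variable control degrades it.
* :func:`rq_panel` — CV% and MFC of the per-sample RQ values; a stable
  control keeps the target's RQ spread close to its true biological
  variation, a variable control inflates it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtTable, ExpressionMatrix
from .stability import gene_stability


@dataclass(frozen=True)
class RQResult:
    sample_id: str
    dct: float
    ddct: float
    rq: float


@dataclass(frozen=True)
class RQPanel:
    results: tuple[RQResult, ...]
    cv_percent: float
    mfc: float


@dataclass(frozen=True)
class CorrelationReport:
    control_gene_id: str
    rho: float
    n: int


def delta_ct(ct_target, ct_control):
    """dCt = Ct(target) - Ct(control), in cycles; NaN propagates."""
    return np.subtract(ct_target, ct_control)


def relative_quantification(dct_sample: float, dct_calibrator: float):
    """ddCt and RQ = 2^(-ddCt) for one sample against the calibrator."""
    ddct = float(dct_sample) - float(dct_calibrator)
    return ddct, float(2.0 ** (-ddct))


def rq_panel(
    ct: CtTable,
    target: str,
    control: str,
    calibrator_samples,
    include_calibrator: bool = False,
) -> RQPanel:
    """Per-sample RQ of ``target`` normalised to ``control``.

    The calibrator dCt is the mean dCt over ``calibrator_samples`` (with a
    single calibrator this is just its dCt). CV% and MFC of the RQ values
    are computed over the non-calibrator samples unless
    ``include_calibrator`` is set — the calibrator's RQ is 1 by
    construction and would only dilute the spread statistics.
    """
    calibrator_samples = list(calibrator_samples)
    if not calibrator_samples:
        raise ValueError("need at least one calibrator sample")
    for g in (target, control):
        if g not in ct.data.index:
            raise KeyError(f"gene {g!r} not in Ct table")
    missing = [s for s in calibrator_samples if s not in ct.data.columns]
    if missing:
        raise KeyError(f"calibrator samples not in Ct table: {missing}")
    dct = delta_ct(ct.data.loc[target], ct.data.loc[control])
    if dct.isna().any():
        bad = list(dct.index[dct.isna()])
        raise ValueError(f"missing Ct for target/control in samples: {bad}")
    dct_cal = float(dct[calibrator_samples].mean())
    results = []
    for sample in ct.data.columns:
        ddct, rq = relative_quantification(float(dct[sample]), dct_cal)
        results.append(RQResult(sample, float(dct[sample]), ddct, rq))
    stat_samples = [
        r for r in results if include_calibrator or r.sample_id not in calibrator_samples
    ]
    rqs = [r.rq for r in stat_samples]
    rec = gene_stability(rqs, gene_id=f"RQ({target}/{control})")
    return RQPanel(results=tuple(results), cv_percent=rec.cv_percent, mfc=rec.mfc)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need >=3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlation_validation(
    matrix: ExpressionMatrix, ct: CtTable, target: str, controls
) -> list[CorrelationReport]:
    """Spearman rho between target RPKM and target dCt for each control.

    Samples are matched by id between the expression matrix and the Ct
    table; at least three shared samples are required. Expected sign is
    negative: higher expression means fewer cycles to threshold.
    """
    shared = [s for s in matrix.sample_ids if s in ct.data.columns]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >=3")
    if target not in matrix.data.index:
        raise KeyError(f"target {target!r} not in expression matrix")
    if target not in ct.data.index:
        raise KeyError(f"target {target!r} not in Ct table")
    rpkm = matrix.data.loc[target, shared].to_numpy(dtype=float)
    reports = []
    for control in controls:
        if control not in ct.data.index:
            raise KeyError(f"control {control!r} not in Ct table")
        dct = delta_ct(
            ct.data.loc[target, shared], ct.data.loc[control, shared]
        ).to_numpy(dtype=float)
        ok = np.isfinite(rpkm) & np.isfinite(dct)
        if ok.sum() < 3:
            raise ValueError(
                f"control {control!r}: <3 complete sample pairs after dropouts"
            )
        rho = spearman_rho(rpkm[ok], dct[ok])
        reports.append(CorrelationReport(control, rho, int(ok.sum())))
    return reports
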