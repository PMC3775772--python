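"""GeNorm expression-consistency M values.

The GeNorm statistic ranks candidate control genes by how well they track
each other: for genes j and k, the pairwise variation V(j,k) is the
standard deviation across samples of log2(q_j / q_k), where q are relative
expression quantities. A gene's M value is the mean of its pairwise
variations against every other candidate. Because only ratios enter,
M is invariant to per-gene and per-sample rescaling; genes whose
expression is a constant multiple of each other have V = 0. Lower M means
more consistent expression.

Quantities are obtained from qPCR Ct values through the standard
efficiency transform q = E^(Ct_min - Ct) (per gene, so the best-expressed
sample has q = 1), or an expression matrix can be used as quantities
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtTable


@dataclass
class GeNormResult:
    m_values: pd.Series  # indexed by gene, ascending M
    exclusion_order: list[str] | None = None  # least stable first
    final_pair: tuple[str, str] | None = None


def ct_to_quantity(ct: CtTable, efficiency: float | pd.Series = 2.0) -> pd.DataFrame:
    """Convert Ct values to relative quantities q = E^(minCt - Ct).

    ``efficiency`` is the per-cycle amplification factor (2.0 = perfect
    doubling), scalar or per-gene Series. Genes with any missing Ct are
    excluded with a warning (GeNorm needs complete rows).
    """
    df = ct.data
    complete = ~df.isna().any(axis=1)
    if not complete.all():
        dropped = list(df.index[~complete])
        warnings.warn(f"excluding genes with missing Ct values: {dropped}")
        df = df.loc[complete]
    if df.empty:
        raise ValueError("no genes with complete Ct rows")
    if isinstance(efficiency, pd.Series):
        eff = efficiency.reindex(df.index)
        if eff.isna().any():
            raise ValueError("efficiency missing for some genes")
        eff_arr = eff.to_numpy(dtype=float)[:, None]
    else:
        eff_arr = float(efficiency)
    if np.any(np.asarray(eff_arr) <= 0):
        raise ValueError("amplification efficiency must be positive")
    if np.any(np.asarray(eff_arr) == 1.0):
        warnings.warn("efficiency 1.0 collapses all quantities to 1 (degenerate)")
    delta = df.min(axis=1).to_numpy()[:, None] - df.to_numpy()
    q = np.power(eff_arr, delta)
    return pd.DataFrame(q, index=df.index, columns=df.columns)


def pairwise_variation(quantities: pd.DataFrame, gene_j: str, gene_k: str) -> float:
    """SD across samples of log2(q_j / q_k); symmetric in (j, k)."""
    for g in (gene_j, gene_k):
        if g not in quantities.index:
            raise KeyError(f"gene {g!r} not in quantity table")
    if quantities.shape[1] < 2:
        raise ValueError("need >=2 samples")
    qj = quantities.loc[gene_j].to_numpy(dtype=float)
    qk = quantities.loc[gene_k].to_numpy(dtype=float)
    if (qj <= 0).any() or (qk <= 0).any():
        raise ValueError("quantities must be strictly positive")
    return float(np.std(np.log2(qj / qk), ddof=1))


def m_values(quantities: pd.DataFrame) -> GeNormResult:
    """GeNorm M per gene: mean pairwise variation against all partners."""
    genes = list(quantities.index)
    if len(genes) < 2:
        raise ValueError("need >=2 genes")
    if quantities.shape[1] < 2:
        raise ValueError("need >=2 samples")
    vals = quantities.to_numpy(dtype=float)
    if (vals <= 0).any() or not np.isfinite(vals).all():
        raise ValueError("quantities must be strictly positive and finite")
    logq = np.log2(vals)
    n = len(genes)
    # V[j,k] = sd of logq_j - logq_k across samples
    diffs = logq[:, None, :] - logq[None, :, :]
    v = diffs.std(axis=2, ddof=1)
    m = v.sum(axis=1) / (n - 1)  # diagonal is 0
    series = pd.Series(m, index=genes, name="M").sort_values(kind="mergesort")
    return GeNormResult(m_values=series)


def stepwise_ranking(quantities: pd.DataFrame) -> GeNormResult:
    """GeNorm stepwise exclusion: drop the least-stable gene repeatedly.

    At each round the gene with the highest M is removed (ties resolved by
    removing the lexicographically larger gene id) and M is recomputed,
    until two genes remain; those form the most-stable final pair.
    """
    if len(quantities.index) < 3:
        raise ValueError("stepwise ranking needs >=3 genes")
    remaining = quantities.copy()
    order: list[str] = []
    full = m_values(quantities)
    while len(remaining.index) > 2:
        m = m_values(remaining).m_values
        worst_m = m.max()
        worst = max(g for g in m.index if m[g] == worst_m)
        order.append(worst)
        remaining = remaining.drop(index=worst)
    pair = tuple(sorted(remaining.index))
    return GeNormResult(m_values=full.m_values, exclusion_order=order, final_pair=pair)


def write_m_values(result: GeNormResult, path) -> None:
    """Export (gene, M) TSV sorted ascending by M."""
    result.m_values.rename_axis("gene").to_frame().to_csv(path, sep="\t")
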