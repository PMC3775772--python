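"""Reading, writing, converting and combining expression matrices and Ct tables.

Expression values are RPKM (reads per kilobase of transcript per million
mapped reads): length- and depth-normalised, so matrices from different
cohorts are directly comparable. Files are plain gene-by-sample TSV/CSV
text with the first row holding sample ids and the first column gene ids.
Decimal commas (European convention) are supported on read and write.

Expression matrices must be complete and non-negative; Ct tables may hold
missing cells (qPCR dropouts happen), represented as NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("ctrlgenes")

_SEPS = {"tab": "\t", "comma": ","}
_DECIMALS = {"point": ".", "comma": ","}


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative finite RPKM values.

    Parameters
    ----------
    data:
        DataFrame with unique gene ids as the index and unique sample ids
        as the columns. All values must be finite and >= 0.
    label:
        Short dataset name, used to namespace samples when cohorts are
        combined.
    """

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index.name = "gene"
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class CtTable:
    """Gene x sample qPCR threshold-cycle values; NaN marks missing wells."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in Ct table")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in Ct table")
        vals = self.data.to_numpy()
        present = ~np.isnan(vals)
        if np.isinf(vals).any():
            raise ValueError("infinite Ct value")
        # Plausibility, not validity: a 40-cycle run cannot produce Ct > ~45.
        if ((vals[present] <= 0) | (vals[present] >= 45)).any():
            warnings.warn("Ct values outside the typical (0, 45) cycle range")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def _read_table(path, dialect: str, decimal_mark: str) -> pd.DataFrame:
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}, got {dialect!r}")
    if decimal_mark not in _DECIMALS:
        raise ValueError(
            f"decimal_mark must be one of {sorted(_DECIMALS)}, got {decimal_mark!r}"
        )
    df = pd.read_csv(
        path,
        sep=_SEPS[dialect],
        decimal=_DECIMALS[decimal_mark],
        index_col=0,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # Convert column by column so errors can name the offending cell.
    out = {}
    for col in df.columns:
        raw = df[col]
        if decimal_mark == "comma":
            raw = raw.str.replace(",", ".", regex=False)
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna()
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{df.loc[gene, col]!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_matrix(
    path, dialect: str = "tab", decimal_mark: str = "point", label: str = ""
) -> ExpressionMatrix:
    """Read a gene x sample RPKM matrix from delimited text.

    The first row must be a sample header and the first column gene ids.
    Duplicate gene ids, ragged rows, non-numeric cells and negative values
    are all rejected with the offending gene/sample named.
    """
    try:
        df = _read_table(path, dialect, decimal_mark)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table in {path}: {exc}") from exc
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing value in row for gene {gene!r} (ragged row?)")
    return ExpressionMatrix(df, label=label or str(path))


def write_matrix(
    matrix: ExpressionMatrix, path, dialect: str = "tab", decimal_mark: str = "point"
) -> None:
    """Write a matrix in the same dialect :func:`read_matrix` accepts."""
    matrix.data.to_csv(
        path,
        sep=_SEPS[dialect],
        decimal=_DECIMALS[decimal_mark],
        index_label="gene",
    )


def read_ct_table(path, dialect: str = "tab", decimal_mark: str = "point") -> CtTable:
    """Read a gene x sample Ct table; empty cells become NaN (missing)."""
    df = _read_table(path, dialect, decimal_mark)
    return CtTable(df)


def write_ct_table(
    ct: CtTable, path, dialect: str = "tab", decimal_mark: str = "point"
) -> None:
    ct.data.to_csv(
        path, sep=_SEPS[dialect], decimal=_DECIMALS[decimal_mark], index_label="gene"
    )


def read_gene_lengths(path, dialect: str = "tab") -> pd.Series:
    """Read a two-column (gene_id, length in bp) table into a Series."""
    df = pd.read_csv(path, sep=_SEPS[dialect], index_col=0)
    lengths = df.iloc[:, 0].astype(int)
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValueError(f"gene length < 1 bp for gene {bad!r}")
    return lengths


def counts_to_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: pd.Series | None = None,
    label: str = "",
) -> ExpressionMatrix:
    """Convert raw read counts to RPKM.

    RPKM(g, s) = counts(g, s) * 1e9 / (length(g) * totals(s)).

    Parameters
    ----------
    counts:
        Gene x sample non-negative read counts.
    lengths:
        Transcript length per gene in base pairs; every gene in ``counts``
        must be present.
    totals:
        Total mapped reads per sample. Defaults to the column sums of
        ``counts``; must be strictly positive.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {list(missing)[:5]}")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.astype(float).reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("per-sample total mapped reads must be positive")
    lens = lengths.astype(float).reindex(counts.index)
    rpkm = counts.mul(1e9).div(lens, axis=0).div(totals, axis=1)
    return ExpressionMatrix(rpkm, label=label)


def combine_datasets(
    matrices: list[ExpressionMatrix], label: str = "combined"
) -> ExpressionMatrix:
    """Pool cohorts column-wise on the intersection of their gene sets.

    Sample ids are namespaced ``"<dataset label>:<sample id>"`` so cohorts
    with clashing sample names can never silently collide. Restricting to
    the common genes guarantees complete rows with no imputation.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = matrices[0].data.index
    for m in matrices[1:]:
        common = common.intersection(m.data.index)
    if len(common) == 0:
        raise ValueError("gene intersection of the datasets is empty")
    # Preserve the first dataset's gene order.
    common = matrices[0].data.index[matrices[0].data.index.isin(common)]
    blocks = []
    for i, m in enumerate(matrices):
        prefix = m.label or f"dataset{i}"
        block = m.data.loc[common].copy()
        block.columns = [f"{prefix}:{s}" for s in block.columns]
        blocks.append(block)
    pooled = pd.concat(blocks, axis=1)
    logger.info(
        "combined %d datasets -> %d genes x %d samples",
        len(matrices),
        pooled.shape[0],
        pooled.shape[1],
    )
    return ExpressionMatrix(pooled, label=label)
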