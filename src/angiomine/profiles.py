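"""Expression tables and the arbitrary-unit (AU) normalisation chain.

Raw tissue expression is TPM-like (EST tags per million library tags). Each
gene's TPM is first divided by beta-actin's TPM in the same tissue, and the
resulting ratio row is then divided by its median across tissues, yielding
dimensionless arbitrary units in which 1.0 means "at the gene's median
tissue". If a gene's median ratio is zero, the median is recomputed over the
strictly positive tissues only; a gene that is zero everywhere is flagged
unexpressed and its AU row is all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ACTIN, HOUSEKEEPING

__all__ = [
    "ExpressionTable",
    "RelativeExpression",
    "read_expression_tsv",
    "actin_normalize",
    "median_normalize",
    "relative_expression",
]


@dataclass
class ExpressionTable:
    """Gene x tissue nonnegative TPM-like matrix with designated reference rows."""

    species: str
    values: pd.DataFrame  # index = gene symbols, columns = tissues
    actin_symbol: str
    housekeeping_symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.empty:
            raise ValueError("empty expression table")
        if v.columns.duplicated().any():
            raise ValueError("duplicate tissue names")
        if v.index.duplicated().any():
            dupes = sorted(set(v.index[v.index.duplicated()]))
            raise ValueError(f"duplicate gene symbols: {dupes}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("non-numeric or non-finite expression value")
        if (arr < 0).any():
            raise ValueError("negative expression value")
        if self.actin_symbol not in v.index:
            raise ValueError("actin row required")
        if (v.loc[self.actin_symbol] <= 0).any():
            raise ValueError("actin row must be strictly positive in every tissue")

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def actin_row(self) -> pd.Series:
        return self.values.loc[self.actin_symbol]


@dataclass
class RelativeExpression:
    """AU matrix (fold-of-median of the actin ratio) plus intermediates."""

    au: pd.DataFrame
    actin_ratio: pd.DataFrame
    unexpressed: pd.Series = field(default=None)  # boolean per gene

    @property
    def tissues(self) -> list[str]:
        return list(self.au.columns)


def read_expression_tsv(path, species: str,
                        actin_symbol: str | None = None,
                        housekeeping_symbols: tuple[str, ...] | None = None,
                        ) -> ExpressionTable:
    """Read a ``symbol<TAB>tissue...`` expression matrix.

    Tissue order is preserved as given; duplicate symbols and non-numeric
    cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError("empty expression table")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression table: {exc}") from None
    return ExpressionTable(
        species=species, values=df,
        actin_symbol=actin_symbol or ACTIN.get(species, "ACTB"),
        housekeeping_symbols=tuple(housekeeping_symbols or HOUSEKEEPING.get(species, ())))


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="symbol")


def actin_normalize(table: ExpressionTable) -> pd.DataFrame:
    """Per-tissue ratio TPM[gene] / TPM[actin]; actin's own row becomes 1."""
    actin = table.actin_row.astype(float)
    if (actin <= 0).any():
        raise ValueError("actin row must be strictly positive in every tissue")
    return table.values.div(actin, axis=1)


def median_normalize(ratios: pd.DataFrame) -> RelativeExpression:
    """Divide each gene's ratio row by its median across tissues.

    A zero median falls back to the median over strictly positive tissues;
    an all-zero row stays all-zero and is flagged unexpressed.
    """
    arr = ratios.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("ratios must be nonnegative")
    au = np.zeros_like(arr)
    unexpressed = np.zeros(arr.shape[0], dtype=bool)
    for i in range(arr.shape[0]):
        row = arr[i]
        m = float(np.median(row))
        if m == 0.0:
            pos = row[row > 0]
            if pos.size == 0:
                unexpressed[i] = True
                continue
            m = float(np.median(pos))
        au[i] = row / m
    return RelativeExpression(
        au=pd.DataFrame(au, index=ratios.index, columns=ratios.columns),
        actin_ratio=ratios,
        unexpressed=pd.Series(unexpressed, index=ratios.index))


def relative_expression(table: ExpressionTable) -> RelativeExpression:
    """Full normalisation chain: actin ratio then fold-of-median AU."""
    return median_normalize(actin_normalize(table))
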