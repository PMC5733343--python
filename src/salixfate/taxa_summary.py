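"""OTU-table filtering and normalization.

Minimal utilities mirroring the 16S processing rules applied downstream
of OTU picking: removal of rare OTUs (total count across all samples of
five or fewer reads), total-sum scaling to relative abundances, and
selection of taxa exceeding a relative-abundance cut in at least one
sample.  OTU tables are plain pandas DataFrames with OTU ids as the index
and one integer count column per sample; an optional taxonomy column
named ``taxonomy`` is carried through untouched.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "filter_rare_otus",
    "total_sum_normalize",
    "abundant_taxa",
]

TAXONOMY_COLUMN = "taxonomy"


def _counts(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns if c != TAXONOMY_COLUMN]
    return table[cols]


def read_otu_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated OTU table (biom-text layout: '#OTU ID' index)."""
    table = pd.read_csv(path, sep="\t", comment=None)
    first = table.columns[0]
    table = table.set_index(first)
    table.index.name = "otu_id"
    return table


def write_otu_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="#OTU ID")


def filter_rare_otus(table: pd.DataFrame, min_total: int = 6) -> pd.DataFrame:
    """Drop OTUs represented by fewer than ``min_total`` reads in total.

    The default keeps OTUs with six or more reads summed across all
    samples, i.e. removes those represented by five or fewer sequences.
    """
    if table.empty:
        return table.copy()
    totals = _counts(table).sum(axis=1)
    return table.loc[totals >= min_total].copy()


def total_sum_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to relative abundances summing to one.

    Idempotent up to floating precision; a sample with zero total raises
    an error naming the sample.
    """
    result = table.copy()
    counts = _counts(table)
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"cannot normalize samples with zero total counts: {zero}")
    result[counts.columns] = counts / totals
    return result


def abundant_taxa(relative_table: pd.DataFrame, threshold: float = 0.01) -> list:
    """OTUs strictly exceeding ``threshold`` relative abundance in any sample."""
    if relative_table.empty:
        return []
    rel = _counts(relative_table)
    mask = (rel > threshold).any(axis=1)
    return relative_table.index[mask].tolist()
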