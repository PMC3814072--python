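"""Contingency-table validation statistics.

Filtered gene lists can be validated against the literature by counting, for
each group of filtered genes, how often its members are co-cited with each
disease.  Arranged as a groups x diseases contingency table, a Pearson
chi-square test of independence asks whether citation frequencies differ by
gene group — i.e. whether each group is preferentially co-cited with its own
disease.  Row/column percentages make the enrichment readable, and Bonferroni
adjustment controls the family-wise error over any follow-up comparisons.

A 3x3 citation-count table for three gene groups (filtered for acute myeloid
leukemia, diffuse large B-cell lymphoma, and breast cancer) ships with the
package; see :func:`load_citation_table`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "load_citation_table",
    "chi_square_independence",
    "table_percentages",
    "bonferroni",
]

MIN_REPRESENTABLE_P = 1e-300


class ContingencyTable:
    """r x c table of non-negative integer counts with row/column labels."""

    def __init__(self, counts, row_labels=None, col_labels=None):
        if isinstance(counts, pd.DataFrame):
            df = counts.copy()
        else:
            df = pd.DataFrame(np.asarray(counts), index=row_labels, columns=col_labels)
        arr = df.to_numpy()
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        self.data = df.astype(np.int64)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def row_labels(self) -> list:
        return list(self.data.index)

    @property
    def col_labels(self) -> list:
        return list(self.data.columns)

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        return cls(pd.read_csv(path, index_col=0))


def load_citation_table() -> ContingencyTable:
    """Cumulative disease co-citation counts for three filtered gene groups.

    Rows are the gene groups (filtered for AML, DLCL and BC respectively);
    columns are the diseases the citations refer to.  Citation counts across
    columns are disjoint by construction of the underlying literature query.
    """
    ref = resources.files("mwnet.data").joinpath("citation_counts.csv")
    with resources.as_file(ref) as path:
        return ContingencyTable.from_csv(path)


def chi_square_independence(t: ContingencyTable, correction: bool = False):
    """Pearson chi-square test of independence.

    Returns ``(statistic, df, p_value)`` with the statistic
    ``sum (O - E)^2 / E`` over all cells, expected counts from the row and
    column marginals, and ``df = (r - 1) * (c - 1)``.  No continuity
    correction by default; ``correction=True`` enables Yates' correction for
    2x2 tables.  P-values below double precision are floored at 1e-300 so a
    bound check like "p < 0.0001" stays meaningful.
    """
    counts = t.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero row or column marginal: test undefined")
    res = sps.chi2_contingency(counts, correction=correction)
    p = max(float(res.pvalue), MIN_REPRESENTABLE_P)
    return float(res.statistic), int(res.dof), p


def table_percentages(t: ContingencyTable):
    """Row and column percentages of a contingency table.

    Returns ``(row_percent, col_percent)`` DataFrames where
    ``row_percent[i, j] = 100 * count / row_total`` and analogously for
    columns, rounded to two decimals.
    """
    counts = t.counts.astype(float)
    row_tot = counts.sum(axis=1, keepdims=True)
    col_tot = counts.sum(axis=0, keepdims=True)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise ValueError("zero row or column total: percentages undefined")
    row = pd.DataFrame(
        np.round(100 * counts / row_tot, 2), index=t.data.index, columns=t.data.columns
    )
    col = pd.DataFrame(
        np.round(100 * counts / col_tot, 2), index=t.data.index, columns=t.data.columns
    )
    return row, col


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: ``min(1, m * p)`` for each p, order preserved.

    ``m`` defaults to the number of p-values and may be larger (when the list
    is a subset of a bigger comparison family), never smaller.
    """
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return list(np.minimum(1.0, m * p))
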