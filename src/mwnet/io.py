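"""Gene expression matrix containers and tabular I/O.

The central container is the :class:`ExpressionMatrix`, an ``N x M`` matrix of
differential expression values (unitless log2-ratio scale) with ``N`` samples
as rows and ``M`` genes (or spots) as columns.  Differential expression is
taken as the binary logarithm of the ratio of a gene's absolute expression
under two conditions (e.g. diseased vs. healthy tissue); log-ratios are
approximately normally distributed, which makes per-sample standard-score
(z-score) normalization appropriate.

Missing measurements (flagged or absent microarray spots) are carried as NaN:
they are excluded from the per-sample mean/standard deviation and are treated
as Neutral by downstream state calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TwoChannelMatrix",
    "read_gem",
    "write_gem",
    "log_ratios",
    "zscore_normalize",
]

_NA_TOKENS = {"", "na", "nan", "null", "none"}


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {kind} identifiers: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of differential expression values.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and gene (or spot)
        identifiers as columns; values are floats, NaN marks missing.
    normalized
        True once per-sample z-score normalization has been applied.
    allow_duplicate_genes
        Permit duplicate column identifiers.  Only meaningful at spot level,
        before replica collapsing maps spots onto genes.
    """

    data: pd.DataFrame
    normalized: bool = False
    allow_duplicate_genes: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "sample")
        if not self.allow_duplicate_genes:
            _check_unique(self.data.columns, "gene")
        if self.normalized:
            self._check_standardized()

    def _check_standardized(self, tol: float = 1e-9) -> None:
        vals = self.data.to_numpy()
        mu = np.nanmean(vals, axis=1)
        sd0 = np.nanstd(vals, axis=1)
        sd1 = np.nanstd(vals, axis=1, ddof=1)
        # unit sd under either the population or the sample convention
        bad = ~(
            np.isclose(mu, 0.0, atol=tol)
            & (np.isclose(sd0, 1.0, atol=tol) | np.isclose(sd1, 1.0, atol=tol))
        )
        if bad.any():
            raise ValueError(
                "normalized=True but rows are not standardized: "
                f"{list(self.data.index[bad][:5])}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]


@dataclass
class TwoChannelMatrix:
    """Paired absolute intensities for two conditions (C1, C2).

    Both channels are samples x genes DataFrames sharing index and columns;
    all intensities must be strictly positive (the log-ratio is undefined
    otherwise).  NaN entries are allowed and propagate as missing.
    """

    values_c1: pd.DataFrame
    values_c2: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values_c1.index.equals(self.values_c2.index):
            raise ValueError("channel sample identifiers differ")
        if not self.values_c1.columns.equals(self.values_c2.columns):
            raise ValueError("channel gene identifiers differ")
        for name, df in (("C1", self.values_c1), ("C2", self.values_c2)):
            arr = df.to_numpy(dtype=float)
            bad = (arr <= 0) & ~np.isnan(arr)
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValueError(
                    f"non-positive intensity in channel {name} at "
                    f"sample {df.index[i]!r}, gene {df.columns[j]!r}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.values_c1.index)

    @property
    def gene_ids(self) -> list:
        return list(self.values_c1.columns)


def read_gem(
    path,
    layout: str = "samples_as_rows",
    delimiter: str = "\t",
    allow_duplicate_genes: bool = False,
) -> ExpressionMatrix:
    """Read a gene expression matrix from delimited text.

    The file carries identifiers in the first row and first column; the body
    is numeric with empty/NA tokens for missing values.  ``layout`` states
    what the file rows are; internally samples are always rows.
    """
    if layout not in ("samples_as_rows", "genes_as_rows"):
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    def parse_cell(val, row, col):
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return np.nan
        s = str(val).strip()
        if s.lower() in _NA_TOKENS:
            return np.nan
        try:
            return float(s)
        except ValueError:
            raise ValueError(
                f"{path}: cannot parse value {s!r} at row {row!r}, column {col!r}"
            ) from None

    parsed = pd.DataFrame(
        [
            [parse_cell(df.iat[i, j], df.index[i], df.columns[j]) for j in range(df.shape[1])]
            for i in range(df.shape[0])
        ],
        index=df.index,
        columns=df.columns,
        dtype=float,
    )
    if layout == "genes_as_rows":
        parsed = parsed.T
    return ExpressionMatrix(parsed, normalized=False, allow_duplicate_genes=allow_duplicate_genes)


def write_gem(
    gem: ExpressionMatrix,
    path,
    layout: str = "samples_as_rows",
    delimiter: str = "\t",
) -> None:
    """Write an expression matrix as delimited text (inverse of read_gem)."""
    if layout not in ("samples_as_rows", "genes_as_rows"):
        raise ValueError(f"unknown layout {layout!r}")
    if gem.n_genes == 0 or gem.n_samples == 0:
        raise ValueError("refusing to write an empty expression matrix")
    df = gem.data if layout == "samples_as_rows" else gem.data.T
    df.to_csv(path, sep=delimiter, float_format="%.17g", na_rep="NA")


def log_ratios(tc: TwoChannelMatrix) -> ExpressionMatrix:
    """Per-element binary logarithm of the C1/C2 intensity ratio."""
    ratio = np.log2(tc.values_c1.to_numpy(dtype=float) / tc.values_c2.to_numpy(dtype=float))
    df = pd.DataFrame(ratio, index=tc.values_c1.index, columns=tc.values_c1.columns)
    return ExpressionMatrix(df, normalized=False, allow_duplicate_genes=True)


def zscore_normalize(gem: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Standard-score normalization of each sample (row).

    Each row i is transformed as ``(e_ij - mu_i) / sigma_i`` with the mean and
    standard deviation of the log-ratios of all genes in that sample, missing
    entries excluded.  ``ddof=0`` (population sigma) is the default; ``ddof=1``
    selects the sample convention.

    Raises
    ------
    ValueError
        If the matrix is already normalized, or a row has fewer than two
        observed values or zero variance.
    """
    if gem.normalized:
        raise ValueError("matrix is already normalized")
    vals = gem.values.copy()
    n_obs = np.sum(~np.isnan(vals), axis=1)
    if (n_obs == 0).any():
        bad = gem.data.index[n_obs == 0][0]
        raise ValueError(f"sample {bad!r} has no observed values")
    if (n_obs < 2).any():
        bad = gem.data.index[n_obs < 2][0]
        raise ValueError(f"sample {bad!r} has fewer than two observed values")
    mu = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=ddof, keepdims=True)
    zero = np.isclose(sd[:, 0], 0.0)
    if zero.any():
        bad = gem.data.index[zero][0]
        raise ValueError(f"sample {bad!r} has zero variance")
    out = (vals - mu) / sd
    df = pd.DataFrame(out, index=gem.data.index, columns=gem.data.columns)
    return ExpressionMatrix(df, normalized=True, allow_duplicate_genes=gem.allow_duplicate_genes)
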