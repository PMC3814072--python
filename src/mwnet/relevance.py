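"""Polarization-based relevance scoring and network filtering.

Every edge of a multi-weighted coexpression network carries four counts
``w = (wOO, wOS, wSO, wSS)``.  A near-uniform ``w`` (e.g. ``(N/4, N/4, N/4,
N/4)``) means the two genes showed no consistent joint behavior across the N
samples and the edge is uninformative; a polarized ``w`` (e.g. ``(N, 0, 0,
0)``) is highly informative.  Each gene g is scored by

    R(g) = (1/D) * sum over neighbors j of
           [1 - min(w_gj) / max(w_gj)] * [2 * sigma(w_gj) / N]

where sigma is the standard deviation of the four weights.  The first factor
vanishes for uniform edges; the second grows with the dispersion of the
weight mass.  With population sigma a single edge contributes at most
sqrt(3)/2 ~= 0.8660, attained by a fully polarized edge (N, 0, 0, 0).

The outer normalization D is N (the sample count) by default, so R rewards
genes with many polarized edges relative to the number of samples.  With
``outer_norm="degree"`` the score is instead the mean polarization of the
gene's edges, bounded by sqrt(3)/2 and independent of how many neighbors the
gene has; a fixed threshold such as 0.5 is then scale-free.  Both readings
are useful; results always record which was used.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd

from .network import edge_weight_vector

__all__ = [
    "edge_polarization",
    "relevance_scores",
    "filter_network",
    "reduction_ratio",
    "reduction_report",
    "format_percent",
    "FilterResult",
]


def edge_polarization(
    w, n_samples: int, sigma_mode: str = "population"
) -> float:
    """Polarization score of one edge weight 4-vector.

    Returns ``(1 - min(w)/max(w)) * (2 * sigma(w) / N)``; 0 for uniform
    vectors, up to sqrt(3)/2 for fully polarized ones (population sigma).
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (4,) or (w < 0).any():
        raise ValueError("w must be a 4-vector of non-negative counts")
    wmax = w.max()
    if wmax == 0:
        raise ValueError("all-zero weight vector: such an edge cannot exist")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    ddof = {"population": 0, "sample": 1}[sigma_mode]
    sigma = float(np.std(w, ddof=ddof))
    return float((1.0 - w.min() / wmax) * (2.0 * sigma / n_samples))


def relevance_scores(
    net: nx.Graph,
    sigma_mode: str = "population",
    outer_norm: str = "n_samples",
) -> pd.DataFrame:
    """Relevance score of every gene in the network.

    Returns a DataFrame indexed by gene with columns ``degree``, ``score``
    and ``rank`` (1 = highest score; ties broken lexicographically by gene
    identifier).  Isolated nodes score 0.
    """
    if outer_norm not in ("n_samples", "degree"):
        raise ValueError(f"unknown outer_norm {outer_norm!r}")
    n = int(net.graph["n_samples"])
    genes = sorted(net.nodes, key=str)
    scores = []
    for g in genes:
        total = 0.0
        deg = net.degree(g)
        for nb in net.neighbors(g):
            total += edge_polarization(
                edge_weight_vector(net, g, nb), n, sigma_mode=sigma_mode
            )
        denom = n if outer_norm == "n_samples" else max(deg, 1)
        scores.append((g, deg, total / denom))
    df = pd.DataFrame(scores, columns=["gene_id", "degree", "score"]).set_index("gene_id")
    # stable sort on (-score, gene_id) gives deterministic ranks
    order = df.sort_values(["score", "gene_id"], ascending=[False, True]).index
    df["rank"] = pd.Series(np.arange(1, len(df) + 1), index=order)
    df.attrs["sigma_mode"] = sigma_mode
    df.attrs["outer_norm"] = outer_norm
    df.attrs["n_samples"] = n
    return df


@dataclass
class FilterResult:
    """Outcome of thresholding a network on the relevance score."""

    kept_genes: list
    removed_genes: list
    reduced_net: nx.Graph
    threshold: float

    @property
    def reduction_ratio(self) -> float:
        total = len(self.kept_genes) + len(self.removed_genes)
        return len(self.removed_genes) / total if total else 0.0


def filter_network(net: nx.Graph, table: pd.DataFrame, threshold: float) -> FilterResult:
    """Keep genes with score >= threshold; drop the rest and their edges."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    missing = [g for g in net.nodes if g not in table.index]
    if missing:
        raise KeyError(f"relevance table does not cover nodes: {missing[:10]}")
    kept = sorted((g for g in net.nodes if table.loc[g, "score"] >= threshold), key=str)
    removed = sorted((g for g in net.nodes if g not in set(kept)), key=str)
    reduced = net.subgraph(kept).copy()
    reduced.graph.update(net.graph)
    return FilterResult(kept, removed, reduced, float(threshold))


def reduction_ratio(n_original: int, n_kept: int) -> float:
    """Fraction of genes removed by filtering."""
    if n_original <= 0:
        raise ValueError("n_original must be positive")
    if not 0 <= n_kept <= n_original:
        raise ValueError("n_kept must be in [0, n_original]")
    return 1.0 - n_kept / n_original


def format_percent(fraction: float, decimals: int = 2) -> str:
    """Render a fraction as a percentage, half-up to ``decimals`` places."""
    q = Decimal(10) ** -decimals
    # scale in Decimal: repr(0.91205) is exact text, 0.91205 * 100 is not
    return f"{(Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)}%"


def reduction_report(results, labels=None) -> pd.DataFrame:
    """Aggregate filtering results across datasets.

    ``results`` is a sequence of FilterResult (or (n_original, n_kept)
    pairs).  Columns: original and filtered gene counts, the exact reduction
    ratio, and the ratio rendered as a half-up two-decimal percentage.
    """
    rows = []
    for res in results:
        if isinstance(res, FilterResult):
            orig = len(res.kept_genes) + len(res.removed_genes)
            kept = len(res.kept_genes)
        else:
            orig, kept = res
        ratio = reduction_ratio(orig, kept)
        rows.append((orig, kept, ratio, format_percent(ratio)))
    df = pd.DataFrame(
        rows,
        columns=["original_genes", "filtered_genes", "reduction_ratio", "reduction_percent"],
    )
    if labels is not None:
        df.index = pd.Index(labels, name="dataset")
    return df
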