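"""Over/silenced state calling and multi-weighted coexpression networks.

A gene is called *over-expressed* in a sample when its normalized differential
expression exceeds a threshold ``epsilon``, *silenced* when it falls below
``-epsilon``, and *neutral* otherwise (strict inequalities; missing values are
neutral).  The multi-weighted coexpression network (MWNET) is an undirected
graph whose nodes are the genes differentially expressed in at least one
sample and whose edges connect genes co-expressed (both non-neutral) in at
least one sample.  Each edge carries a 4-vector of counts

    (wOO, wOS, wSO, wSS)

tallying, across samples, the joint state of the two endpoint genes: both
over, first over / second silenced, the converse, and both silenced.  The
"first" gene of an edge is the lexicographically smaller identifier; querying
the edge from the other endpoint swaps wOS and wSO.

Edges with weight mass concentrated in one coordinate indicate a consistent
joint behavior (mutual enhancement for OO/SS, a negative-loop-like relation
for OS/SO); near-uniform weight vectors indicate uninformative co-expression.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "OVER",
    "NEUTRAL",
    "SILENCED",
    "StateMatrix",
    "call_states",
    "collapse_replicas",
    "build_mwnet",
    "edge_weight_vector",
    "write_network",
    "read_network",
]

OVER = 1
NEUTRAL = 0
SILENCED = -1

WEIGHT_KEYS = ("wOO", "wOS", "wSO", "wSS")


@dataclass
class StateMatrix:
    """Per-sample, per-gene ternary calls (+1 over, 0 neutral, -1 silenced).

    ``data`` is a samples x genes DataFrame of int8; ``epsilon`` records the
    threshold that produced the calls.
    """

    data: pd.DataFrame
    epsilon: float

    def __post_init__(self) -> None:
        self.data = self.data.astype(np.int8)
        # string identifiers make the lexicographic edge convention unambiguous
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        vals = self.data.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("states must be in {-1, 0, +1}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def call_states(
    gem: ExpressionMatrix, epsilon: float = 0.0, require_normalized: bool = True
) -> StateMatrix:
    """Call over/silenced/neutral states at threshold ``epsilon``.

    Strict comparison: ``e > epsilon`` is over, ``e < -epsilon`` silenced,
    everything else (including ``e == epsilon``, ``e == 0`` at ``epsilon=0``,
    and missing values) is neutral.  By default the matrix must be z-score
    normalized; pass ``require_normalized=False`` to call on raw log-ratios.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if require_normalized and not gem.normalized:
        raise ValueError(
            "expression matrix is not normalized; normalize first or pass "
            "require_normalized=False"
        )
    vals = gem.values
    states = np.zeros(vals.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        states[vals > epsilon] = OVER
        states[vals < -epsilon] = SILENCED
    df = pd.DataFrame(states, index=gem.data.index, columns=gem.data.columns)
    return StateMatrix(df, epsilon=float(epsilon))


def collapse_replicas(
    states: StateMatrix,
    replica_map: Mapping[str, str],
    policy: str = "any_replica",
    gem: ExpressionMatrix | None = None,
) -> StateMatrix:
    """Collapse replica spots onto genes, one column per gene.

    Old spotted arrays measured each gene on several replica spots; a gene is
    treated as differentially expressed in a sample if at least one of its
    replicas is.

    policy="any_replica" (default)
        A gene is non-neutral iff >= 1 replica is; if all non-neutral replicas
        agree in sign that sign wins, while replicas conflicting in sign
        (some over, some silenced) collapse to neutral — disagreeing replicas
        indicate an unreliable spot.
    policy="max_magnitude"
        The replica with the largest absolute expression decides; requires the
        source expression matrix via ``gem``.
    """
    if policy not in ("any_replica", "max_magnitude"):
        raise ValueError(f"unknown replica policy {policy!r}")
    spots = states.gene_ids
    missing = [s for s in spots if s not in replica_map]
    if missing:
        raise KeyError(f"spots absent from replica map: {missing[:10]}")
    if policy == "max_magnitude":
        if gem is None:
            raise ValueError("policy='max_magnitude' requires the expression matrix (gem)")
        if list(gem.data.columns) != spots or list(gem.data.index) != states.sample_ids:
            raise ValueError("expression matrix does not match the state matrix")

    genes = sorted({replica_map[s] for s in spots})
    gene_pos = {g: k for k, g in enumerate(genes)}
    svals = states.data.to_numpy()
    n = states.n_samples
    out = np.zeros((n, len(genes)), dtype=np.int8)

    if policy == "any_replica":
        pos = np.zeros((n, len(genes)), dtype=bool)
        neg = np.zeros((n, len(genes)), dtype=bool)
        for j, spot in enumerate(spots):
            k = gene_pos[replica_map[spot]]
            pos[:, k] |= svals[:, j] == OVER
            neg[:, k] |= svals[:, j] == SILENCED
        out[pos & ~neg] = OVER
        out[neg & ~pos] = SILENCED
    else:
        evals = np.nan_to_num(gem.values, nan=0.0)
        best = np.full((n, len(genes)), -1.0)
        for j, spot in enumerate(spots):
            k = gene_pos[replica_map[spot]]
            mag = np.abs(evals[:, j])
            take = mag > best[:, k]
            out[take, k] = svals[take, j]
            best[take, k] = mag[take]

    df = pd.DataFrame(out, index=states.data.index, columns=genes)
    return StateMatrix(df, epsilon=states.epsilon)


def _weight_channel(sa: int, sb: int) -> int:
    # 0=OO, 1=OS, 2=SO, 3=SS for the (canonically ordered) pair (a, b)
    return (sa == SILENCED) * 2 + (sb == SILENCED)


def build_mwnet(states: StateMatrix) -> nx.Graph:
    """Build the multi-weighted coexpression network from a state matrix.

    Returns an undirected :class:`networkx.Graph` whose nodes are the genes
    non-neutral in at least one sample (node attribute ``n_expressed`` counts
    those samples) and whose edges carry integer attributes wOO/wOS/wSO/wSS
    with respect to lexicographic endpoint order.  The graph attribute
    ``n_samples`` records N; ``epsilon`` the calling threshold.

    Each sample contributes exactly one unit to exactly one weight of every
    pair of genes it co-expresses, so edge weight sums lie in [1, N].
    """
    if states.n_samples < 1:
        raise ValueError("state matrix has no samples")
    order = np.argsort(np.asarray(states.gene_ids, dtype=object))
    genes = [states.gene_ids[k] for k in order]
    vals = states.data.to_numpy()[:, order]
    m = len(genes)

    weights: dict[tuple[int, int], np.ndarray] = {}
    for row in vals:
        nz = np.flatnonzero(row)
        if nz.size < 2:
            continue
        s = row[nz]
        ii, jj = np.triu_indices(nz.size, k=1)
        chans = (s[ii] == SILENCED) * 2 + (s[jj] == SILENCED)
        for a, b, c in zip(nz[ii], nz[jj], chans):
            key = (int(a), int(b))
            w = weights.get(key)
            if w is None:
                w = np.zeros(4, dtype=np.int64)
                weights[key] = w
            w[c] += 1

    g = nx.Graph(n_samples=states.n_samples, epsilon=states.epsilon)
    expressed = np.count_nonzero(vals, axis=0)
    for k in np.flatnonzero(expressed):
        g.add_node(genes[k], n_expressed=int(expressed[k]))
    for (a, b), w in weights.items():
        g.add_edge(genes[a], genes[b], **dict(zip(WEIGHT_KEYS, map(int, w))))
    return g


def edge_weight_vector(net: nx.Graph, a, b) -> np.ndarray:
    """Weight 4-vector (wOO, wOS, wSO, wSS) of edge (a, b) as seen from a.

    The stored orientation uses the lexicographically smaller endpoint first;
    querying from the larger endpoint returns the vector with wOS and wSO
    swapped.
    """
    d = net.edges[a, b]
    w = np.array([d[k] for k in WEIGHT_KEYS], dtype=np.int64)
    if str(a) > str(b):
        w = w[[0, 2, 1, 3]]
    return w


def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Write a network as GraphML or as a canonical TSV edge list.

    The TSV has columns gene_a, gene_b, wOO, wOS, wSO, wSS with gene_a <
    gene_b lexicographically; a node-list sidecar ``<path>.nodes.tsv`` records
    every node with its per-gene non-neutral sample count, so isolated nodes
    survive a round trip.
    """
    if format == "graphml":
        nx.write_graphml(net, path)
        return
    if format != "edge_tsv":
        raise ValueError(f"unknown network format {format!r}")
    path = str(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_a", "gene_b", *WEIGHT_KEYS])
        for a, b in sorted(tuple(sorted((str(u), str(v)))) for u, v in net.edges):
            w = edge_weight_vector(net, a, b)
            writer.writerow([a, b, *map(int, w)])
    with open(path + ".nodes.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "n_expressed", "n_samples", "epsilon"])
        for node in sorted(net.nodes, key=str):
            writer.writerow(
                [
                    node,
                    net.nodes[node].get("n_expressed", ""),
                    net.graph.get("n_samples", ""),
                    net.graph.get("epsilon", ""),
                ]
            )


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    """Inverse of :func:`write_network`."""
    if format == "graphml":
        g = nx.read_graphml(path)
        h = nx.Graph(
            n_samples=int(g.graph.get("n_samples", 0)),
            epsilon=float(g.graph.get("epsilon", 0.0)),
        )
        for node, d in g.nodes(data=True):
            h.add_node(node, n_expressed=int(d.get("n_expressed", 0)))
        for u, v, d in g.edges(data=True):
            a, b = sorted((str(u), str(v)))
            w = {k: int(d[k]) for k in WEIGHT_KEYS}
            if (a, b) != (str(u), str(v)):
                w["wOS"], w["wSO"] = w["wSO"], w["wOS"]
            h.add_edge(a, b, **w)
        return h
    if format != "edge_tsv":
        raise ValueError(f"unknown network format {format!r}")
    path = str(path)
    nodes = pd.read_csv(path + ".nodes.tsv", sep="\t", dtype={"gene_id": str})
    g = nx.Graph()
    if len(nodes):
        g.graph["n_samples"] = int(nodes["n_samples"].iloc[0])
        g.graph["epsilon"] = float(nodes["epsilon"].iloc[0])
    for _, row in nodes.iterrows():
        g.add_node(row["gene_id"], n_expressed=int(row["n_expressed"]))
    edges = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for _, row in edges.iterrows():
        g.add_edge(
            row["gene_a"], row["gene_b"], **{k: int(row[k]) for k in WEIGHT_KEYS}
        )
    return g
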