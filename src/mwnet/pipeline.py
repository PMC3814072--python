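"""End-to-end run: normalize -> call -> collapse -> build -> score -> filter.

`run_pipeline` drives the whole analysis from an expression matrix on disk to
a filtered gene list, writing every intermediate artifact plus a JSON
manifest capturing the parameters and library versions, so a run can be
reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx
import numpy
import pandas

from . import __version__
from .io import read_gem, write_gem, zscore_normalize
from .network import build_mwnet, call_states, collapse_replicas, write_network
from .relevance import (
    FilterResult,
    filter_network,
    reduction_report,
    relevance_scores,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("mwnet")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults: epsilon 0, threshold 0.5)."""

    input_path: str
    output_dir: str
    epsilon: float = 0.0
    relevance_threshold: float = 0.5
    sigma_mode: str = "population"
    outer_norm: str = "n_samples"
    normalization: bool = True
    replica_map_path: str | None = None
    replica_policy: str = "any_replica"
    layout: str = "samples_as_rows"
    delimiter: str = "\t"
    seed: int = 0
    log_level: str = "INFO"


def _read_replica_map(path: str, delimiter: str) -> dict:
    df = pandas.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: replica map needs spot_id and gene_id columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def run_pipeline(config: RunConfig) -> FilterResult:
    """Execute the full filtering pipeline and write artifacts to disk."""
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    gem = read_gem(
        config.input_path,
        layout=config.layout,
        delimiter=config.delimiter,
        allow_duplicate_genes=config.replica_map_path is not None,
    )
    logger.info("read %d samples x %d genes", gem.n_samples, gem.n_genes)

    if config.normalization:
        gem = zscore_normalize(gem)
        write_gem(gem, out / "normalized_gem.tsv")
        logger.info("normalized per-sample (z-score)")

    states = call_states(gem, config.epsilon, require_normalized=config.normalization)
    if config.replica_map_path is not None:
        rmap = _read_replica_map(config.replica_map_path, config.delimiter)
        states = collapse_replicas(states, rmap, policy=config.replica_policy, gem=gem)
        logger.info("collapsed %d spots -> %d genes", gem.n_genes, len(states.gene_ids))

    net = build_mwnet(states)
    write_network(net, out / "network.tsv", format="edge_tsv")
    logger.info(
        "network: %d nodes, %d edges (epsilon=%g)",
        net.number_of_nodes(),
        net.number_of_edges(),
        config.epsilon,
    )

    table = relevance_scores(net, sigma_mode=config.sigma_mode, outer_norm=config.outer_norm)
    table.to_csv(out / "relevance.tsv", sep="\t")

    result = filter_network(net, table, config.relevance_threshold)
    write_network(result.reduced_net, out / "reduced_network.tsv", format="edge_tsv")
    pandas.Series(result.kept_genes, name="gene_id").to_csv(
        out / "filtered_genes.tsv", sep="\t", index=False
    )
    report = reduction_report([result], labels=["run"])
    report.to_csv(out / "reduction_report.tsv", sep="\t")
    logger.info(
        "filtered: kept %d / %d genes (reduction %s)",
        len(result.kept_genes),
        len(result.kept_genes) + len(result.removed_genes),
        report["reduction_percent"].iloc[0],
    )

    manifest = {
        "config": asdict(config),
        "versions": {
            "mwnet": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
        "network": {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()},
        "kept_genes": len(result.kept_genes),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result
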