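"""Synthetic two-condition expression data with planted polarized modules.

The generator emulates the kind of data the pipeline targets: a samples x
genes matrix of log2-ratios in which most genes are background noise
(log-ratios are approximately normal, so background draws are i.i.d.
Gaussian) and a few small gene *modules* behave coherently.  In samples
where a module is active (with probability ``p_on``), member genes draw a
signal magnitude ``|Normal(mu_sig, sigma_sig)|`` whose signs follow the
module pattern:

- ``OO``  all members over-expressed (mutual enhancement),
- ``SS``  all members silenced,
- ``OS``  a designated half over-expressed, the other half silenced
          (a negative-loop-like relation).

In inactive samples module genes fall back to background noise.  Pairwise
states within a module are therefore polarized toward one of the four joint
behaviors, while background genes still form plenty of spurious edges at
epsilon=0 — exactly what the relevance filter must cut through.

Each gene may be printed on several replica spots (noisy copies with
background-sd jitter) sharing a spot-to-gene map, mimicking spot duplication
on old spotted arrays.

Randomness uses one master seed with independent sub-streams per module and
for the background block, so adding a module never perturbs background draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["ModuleSpec", "SyntheticConfig", "generate", "recovery_metrics"]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: size genes moving together with pattern signs."""

    size: int = 4
    pattern: str = "OO"
    p_on: float = 0.9
    mu_sig: float = 2.0
    sigma_sig: float = 0.5

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if self.pattern not in ("OO", "OS", "SS"):
            raise ValueError(f"unknown module pattern {self.pattern!r}")
        if not 0 < self.p_on <= 1:
            raise ValueError("p_on must be in (0, 1]")
        if self.mu_sig <= 0 or self.sigma_sig < 0:
            raise ValueError("need mu_sig > 0 and sigma_sig >= 0")


def _default_modules():
    return [
        ModuleSpec(pattern="OO"),
        ModuleSpec(pattern="SS"),
        ModuleSpec(pattern="OS"),
    ]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic scenario.

    Defaults describe the reference recovery scenario: 20 samples, 200
    background genes, three planted 4-gene modules (one per pattern) active
    in 90% of samples with signal mean 2 on a unit-sd background.
    """

    n_samples: int = 20
    n_background_genes: int = 200
    modules: list = field(default_factory=_default_modules)
    background_sd: float = 1.0
    replica_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_background_genes < 0:
            raise ValueError("need n_samples >= 1 and n_background_genes >= 0")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        if self.replica_count < 1:
            raise ValueError("replica_count must be >= 1")
        self.modules = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.modules
        ]


def generate(config: SyntheticConfig):
    """Generate a synthetic expression matrix plus ground-truth labels.

    Returns
    -------
    gem : ExpressionMatrix
        Unnormalized log-ratio matrix.  With ``replica_count == 1`` columns
        are gene identifiers; otherwise columns are spot identifiers
        (``<gene>_r<k>``) and the replica map is needed downstream.
    truth : dict
        gene_id -> "background" or "module-<k>".
    replica_map : dict
        spot_id -> gene_id (identity when replica_count == 1).
    """
    n = config.n_samples
    master = np.random.SeedSequence(config.seed)
    # fixed spawn layout: background, one stream per module, replica jitter
    streams = master.spawn(len(config.modules) + 2)
    bg_rng = np.random.default_rng(streams[0])
    jitter_rng = np.random.default_rng(streams[-1])

    gene_ids: list[str] = []
    truth: dict[str, str] = {}
    columns: list[np.ndarray] = []

    n_module_genes = sum(m.size for m in config.modules)
    n_digits = max(3, len(str(n_module_genes + config.n_background_genes)))

    for k, (mod, stream) in enumerate(zip(config.modules, streams[1:-1]), start=1):
        rng = np.random.default_rng(stream)
        active = rng.random(n) < mod.p_on
        signs = np.ones(mod.size)
        if mod.pattern == "SS":
            signs[:] = -1
        elif mod.pattern == "OS":
            signs[mod.size // 2 :] = -1
        for g in range(mod.size):
            gid = f"MOD{k}_{mod.pattern}_{g + 1:02d}"
            magnitude = np.abs(rng.normal(mod.mu_sig, mod.sigma_sig, size=n))
            noise = rng.normal(0.0, config.background_sd, size=n)
            vals = np.where(active, signs[g] * magnitude, noise)
            gene_ids.append(gid)
            truth[gid] = f"module-{k}"
            columns.append(vals)

    bg = bg_rng.normal(0.0, config.background_sd, size=(n, config.n_background_genes))
    for g in range(config.n_background_genes):
        gid = f"BG{g + 1:0{n_digits}d}"
        gene_ids.append(gid)
        truth[gid] = "background"
        columns.append(bg[:, g])

    values = np.column_stack(columns) if columns else np.empty((n, 0))

    if config.replica_count == 1:
        spot_ids = list(gene_ids)
        replica_map = {g: g for g in gene_ids}
        data = values
    else:
        spot_ids, spot_cols, replica_map = [], [], {}
        for j, gid in enumerate(gene_ids):
            for r in range(1, config.replica_count + 1):
                sid = f"{gid}_r{r}"
                spot_ids.append(sid)
                replica_map[sid] = gid
                jitter = jitter_rng.normal(0.0, config.background_sd, size=n)
                spot_cols.append(values[:, j] + jitter)
        data = np.column_stack(spot_cols)

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    df = pd.DataFrame(data, index=sample_ids, columns=spot_ids)
    gem = ExpressionMatrix(df, normalized=False, allow_duplicate_genes=True)
    return gem, truth, replica_map


def recovery_metrics(table: pd.DataFrame, truth: dict) -> dict:
    """How well planted genes separate from background in a relevance table.

    Genes absent from the table (never differentially expressed, hence not in
    the network) count as scoring 0 at the bottom of the ranking.

    Returns a dict with:

    worst_planted_rank
        Largest (worst) rank among planted module genes.
    background_quantiles
        5/25/50/75/95th percentiles of background scores.
    background_above_planted
        Fraction of background genes scoring above the lowest-scoring planted
        gene, counting ties as 1/2 (mid-rank convention); 0 means perfect
        separation, and a table of all-equal scores gives 0.5.
    """
    missing = [g for g in table.index if g not in truth]
    if missing:
        raise KeyError(f"truth does not cover genes: {missing[:10]}")
    scores = {g: 0.0 for g in truth}
    ranks = {g: len(truth) for g in truth}
    for g in table.index:
        scores[g] = float(table.loc[g, "score"])
        ranks[g] = int(table.loc[g, "rank"])
    planted = [g for g, lab in truth.items() if lab != "background"]
    background = [g for g, lab in truth.items() if lab == "background"]
    if not planted or not background:
        raise ValueError("truth must contain both planted and background genes")
    bg_scores = np.array([scores[g] for g in background])
    floor = min(scores[g] for g in planted)
    above = float(np.sum(bg_scores > floor) + 0.5 * np.sum(bg_scores == floor))
    return {
        "worst_planted_rank": max(ranks[g] for g in planted),
        "background_quantiles": {
            q: float(np.percentile(bg_scores, q)) for q in (5, 25, 50, 75, 95)
        },
        "background_above_planted": above / len(background),
    }
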