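"""Scikit-learn estimators wrapping the network-filtering pipeline.

:class:`MWNetGeneFilter` is the headline object: a feature selector in the
scikit-learn sense (``fit`` / ``transform`` / ``get_support``) implementing
multivariate gene filtering.  Fitting a samples x genes matrix of
differential expression values builds the multi-weighted coexpression
network, scores every gene by the polarization of its edges, and keeps the
genes whose relevance score clears a threshold; ``transform`` then reduces
any matrix with the same columns to the selected genes.  It composes with
``sklearn.pipeline.Pipeline`` and model selection like any other selector.

:class:`SampleZScoreNormalizer` standardizes each *row* (sample) of the
matrix — the per-sample z-score normalization appropriate for log-ratio
microarray data — unlike the column-wise ``StandardScaler``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import ExpressionMatrix, zscore_normalize
from .network import build_mwnet, call_states, collapse_replicas
from .relevance import filter_network, relevance_scores

__all__ = ["SampleZScoreNormalizer", "MWNetGeneFilter"]


class SampleZScoreNormalizer(TransformerMixin, BaseEstimator):
    """Standardize every sample (row) to mean 0 and standard deviation 1.

    Parameters
    ----------
    ddof : int, default=0
        0 for population standard deviation, 1 for the sample convention.

    The transform is stateless (each row is standardized with its own mean
    and sd, missing values excluded); ``fit`` only records the input schema.
    """

    def __init__(self, ddof: int = 0):
        self.ddof = ddof

    def fit(self, X, y=None):
        validate_data(self, X, dtype=float, ensure_all_finite="allow-nan")
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(
            self, X, dtype=float, ensure_all_finite="allow-nan", reset=False
        )
        mu = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, ddof=self.ddof, keepdims=True)
        if np.isclose(sd, 0.0).any():
            raise ValueError("zero-variance sample cannot be standardized")
        return (X - mu) / sd

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        tags.requires_fit = False
        return tags


class MWNetGeneFilter(SelectorMixin, BaseEstimator):
    """Select disease-relevant genes via a multi-weighted coexpression network.

    For each sample a gene is called over-expressed (normalized differential
    expression > ``epsilon``), silenced (< ``-epsilon``) or neutral.  Genes
    expressed in at least one sample become network nodes; an edge between two
    genes counts, across samples, the four joint states (over/over,
    over/silenced, silenced/over, silenced/silenced).  Each gene's relevance
    score aggregates the polarization of its edges — uniform state counts
    score zero, concentrated ones score high — and genes at or above
    ``threshold`` are kept.

    Parameters
    ----------
    epsilon : float, default=0.0
        Differential-expression call threshold (0 = any fold change).
    threshold : float, default=0.5
        Relevance score cut; genes with score >= threshold are kept.
    normalize : bool, default=True
        Apply per-sample z-score normalization before state calling.
    sigma_mode : {"population", "sample"}, default="population"
        Standard-deviation convention for the four edge weights.
    outer_norm : {"n_samples", "degree"}, default="n_samples"
        Divide each gene's summed edge polarization by the sample count
        (score grows with the number of polarized edges) or by the gene's
        degree (mean edge polarization, bounded by sqrt(3)/2 ~ 0.866, making
        a fixed threshold scale-free).
    replica_map : dict or None, default=None
        spot_id -> gene_id map; when given, input columns are replica spots
        and a gene counts as expressed if at least one replica is.
    replica_policy : {"any_replica", "max_magnitude"}, default="any_replica"
        Conflict resolution when replicas disagree in sign.
    ddof : int, default=0
        Degrees-of-freedom correction for the per-sample normalization.

    Attributes
    ----------
    network_ : networkx.Graph
        The multi-weighted coexpression network (edge attributes
        wOO/wOS/wSO/wSS; graph attribute n_samples).
    relevance_table_ : pandas.DataFrame
        Per-gene degree, relevance score and rank.
    filter_result_ : FilterResult
        Kept/removed gene lists and the reduced network.
    relevance_ : ndarray of shape (n_features_in_,)
        Relevance score per input feature (0 for genes absent from the
        network, i.e. never differentially expressed).
    support_ : ndarray of bool of shape (n_features_in_,)
        True for features whose gene was kept.

    Examples
    --------
    >>> from mwnet.synthetic import SyntheticConfig, generate
    >>> gem, truth, _ = generate(SyntheticConfig(seed=7))
    >>> sel = MWNetGeneFilter(outer_norm="degree", threshold=0.5)
    >>> reduced = sel.fit_transform(gem.data)
    >>> reduced.shape[0] == gem.data.shape[0]
    True
    """

    def __init__(
        self,
        epsilon: float = 0.0,
        threshold: float = 0.5,
        normalize: bool = True,
        sigma_mode: str = "population",
        outer_norm: str = "n_samples",
        replica_map: dict | None = None,
        replica_policy: str = "any_replica",
        ddof: int = 0,
    ):
        self.epsilon = epsilon
        self.threshold = threshold
        self.normalize = normalize
        self.sigma_mode = sigma_mode
        self.outer_norm = outer_norm
        self.replica_map = replica_map
        self.replica_policy = replica_policy
        self.ddof = ddof

    def fit(self, X, y=None):
        """Build the network from X (samples x genes) and select genes."""
        feature_names = list(X.columns.astype(str)) if isinstance(X, pd.DataFrame) else None
        Xv = validate_data(
            self, X, dtype=float, ensure_all_finite="allow-nan", ensure_min_samples=1
        )
        if feature_names is None:
            width = len(str(Xv.shape[1]))
            feature_names = [f"g{j + 1:0{width}d}" for j in range(Xv.shape[1])]
        sample_ids = [f"s{i + 1}" for i in range(Xv.shape[0])]
        gem = ExpressionMatrix(
            pd.DataFrame(Xv, index=sample_ids, columns=feature_names),
            allow_duplicate_genes=self.replica_map is not None,
        )
        if self.normalize:
            gem = zscore_normalize(gem, ddof=self.ddof)
        states = call_states(gem, self.epsilon, require_normalized=self.normalize)
        if self.replica_map is not None:
            states = collapse_replicas(
                states, self.replica_map, policy=self.replica_policy, gem=gem
            )
        self.network_ = build_mwnet(states)
        self.relevance_table_ = relevance_scores(
            self.network_, sigma_mode=self.sigma_mode, outer_norm=self.outer_norm
        )
        self.filter_result_ = filter_network(
            self.network_, self.relevance_table_, self.threshold
        )
        kept = set(self.filter_result_.kept_genes)
        scores = self.relevance_table_["score"]
        to_gene = self.replica_map if self.replica_map is not None else {}
        self.relevance_ = np.array(
            [float(scores.get(to_gene.get(f, f), 0.0)) for f in feature_names]
        )
        self.support_ = np.array([to_gene.get(f, f) in kept for f in feature_names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        return tags
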