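# mwnet

Multi-weighted gene coexpression networks and polarization-based gene
filtering for two-condition expression data.

## The problem

Coexpression networks built from microarray-style differential expression
data are large, dense, and full of false-positive interactions. Before any
downstream analysis (motif discovery, biomarker candidate selection) the
network has to be filtered down to the genes whose behavior across samples is
actually informative. Univariate filters ignore how genes move *together*;
this package implements a fast multivariate filter that works directly on the
topology of a specially labeled network.

## The method

Expression for `N` samples and `M` genes is organized as a gene expression
matrix `GEM : N x M`, with each entry the binary log-ratio of a gene's
absolute expression under two conditions (e.g. diseased vs. healthy),
z-score-normalized per sample:

    e_ij = ( log2(eC1_ij / eC2_ij) - mu_i ) / sigma_i

A gene is **over-expressed** in a sample when `e_ij > eps`, **silenced** when
`e_ij < -eps`, neutral otherwise. The **multi-weighted coexpression network**
has a node for every gene differentially expressed in at least one sample and
an edge between genes co-expressed in at least one sample; each edge carries
four counts

    w = (wOO, wOS, wSO, wSS)

of how many samples showed each joint state (over/over, over/silenced,
silenced/over, silenced/silenced). A near-uniform `w` (e.g. `(N/4, N/4, N/4,
N/4)`) is uninformative; a polarized one (e.g. `(N, 0, 0, 0)`) indicates a
consistent joint behavior. Each gene is scored by

    R(g) = (1/D) * sum_{j : (g, g_j) in E} [1 - min(w)/max(w)] * [2 sigma(w) / N]

and genes with `R >= threshold` are kept. `D = N` by default (the score grows
with the number of polarized edges relative to the sample count);
`outer_norm="degree"` uses `D = degree(g)` instead, giving the mean edge
polarization, bounded by `sqrt(3)/2 ~ 0.866` and independent of network size.

The package also ships the contingency-table validation statistics used to
check filtered gene lists against literature co-citation counts (Pearson
chi-square test of independence, row/column percentages, Bonferroni
adjustment) together with a 3x3 citation-count table for three diseases
(acute myeloid leukemia, diffuse large B-cell lymphoma, breast cancer), and a
synthetic-data generator with planted polarized modules so the whole pipeline
is testable end to end without downloads.

## Worked example

Generate the reference synthetic scenario (20 samples, 200 background genes,
three planted 4-gene modules active in 90% of samples) and run the pipeline:

```sh
$ mwnet synth demo --seed 7
wrote 20x212 matrix to demo
$ mwnet pipeline demo/gem.tsv demo/run --outer-norm degree --threshold 0.4
INFO read 20 samples x 212 genes
INFO normalized per-sample (z-score)
INFO network: 212 nodes, 22366 edges (epsilon=0)
INFO filtered: kept 12 / 212 genes (reduction 94.34%)
```

At `eps = 0` every gene joins the network and the graph is dense (22,366
edges), but the mean edge polarization separates the planted modules from the
background: the 12 kept genes in `demo/run/filtered_genes.tsv` are exactly
the 12 planted module genes (`MOD1_OO_01` ... `MOD3_OS_04`), a 94.34%
reduction. `demo/run/relevance.tsv` holds the per-gene degree, score and
rank; background genes score around 0.1-0.2 while planted genes exceed 0.4.

The same analysis as a scikit-learn feature selector:

```python
from mwnet import MWNetGeneFilter
from mwnet.synthetic import SyntheticConfig, generate

gem, truth, _ = generate(SyntheticConfig(seed=7))
sel = MWNetGeneFilter(outer_norm="degree", threshold=0.4)
X_reduced = sel.fit_transform(gem.data)   # (20, 12)
sel.relevance_table_.head()               # degree, score, rank per gene
```

`MWNetGeneFilter` follows the selector API (`get_support`, `transform`,
`get_params`) and composes with `sklearn.pipeline.Pipeline`.

Validation statistics on the shipped citation table:

```python
from mwnet import chi_square_independence, load_citation_table
stat, df, p = chi_square_independence(load_citation_table())
# stat = 64897.4, df = 4, p < 0.0001
```

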