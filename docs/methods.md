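# Methods

## Model and pipeline

The pipeline turns a two-condition expression experiment into a short list of
candidate disease-relevant genes in five steps.

1. **Differential expression.** Input is either a precomputed samples x genes
   log2-ratio matrix or paired positive intensity channels, from which
   `log_ratios` computes `log2(C1/C2)` per cell. Log-ratios are close to
   normally distributed, which justifies step 2.
2. **Per-sample z-score normalization.** Each sample (row) is standardized
   with the mean and standard deviation of all genes in that sample. Missing
   entries (flagged or absent spots) are excluded from the moments and stay
   missing. Population sigma (`ddof=0`) is the default; a `ddof=1` switch
   gives the sample convention for comparison. Rows with zero variance or
   fewer than two observations are rejected rather than silently propagated.
3. **State calling.** At threshold `eps >= 0`, a gene is over-expressed in a
   sample if `e > eps`, silenced if `e < -eps`, neutral otherwise. The
   comparison is strict, so `e = eps` (and in particular `e = 0` at
   `eps = 0`) is neutral, and missing values are neutral. `eps = 0`
   (any fold change, "1-folding") is the default working point.
4. **Replica collapsing (optional).** When genes are printed on several
   replica spots, a spot-to-gene map collapses columns: a gene is expressed
   in a sample if at least one replica is. If non-neutral replicas agree in
   sign, that sign wins; under the default `any_replica` policy replicas that
   conflict in sign collapse to neutral, because disagreeing replicas mark an
   unreliable measurement. The alternative `max_magnitude` policy lets the
   replica with the largest |e| decide; it needs the expression magnitudes,
   so it takes the expression matrix as an extra argument.
5. **Network, score, filter.** Nodes are genes expressed in >= 1 sample;
   edges connect genes co-expressed in >= 1 sample (no minimum-support
   pre-filter — filtering is the relevance score's job); each co-expressing
   sample increments exactly one of the four edge weights. Genes are scored
   by summed edge polarization (below) and kept when `R >= threshold`
   (inclusive comparison; the default threshold is 0.5, a deliberately
   relaxed cut that keeps genes informative in only a subset of samples —
   useful when a disease has several phenotypes).

## The relevance score

For an edge with weights `w` built from `N` samples,

    pol(w) = [1 - min(w)/max(w)] * [2 * sigma(w) / N]

The first factor kills uniform edges; the second rewards dispersion of the
weight mass. `sigma` is the population standard deviation of the four counts
by default — the 4-vector is the complete set of state counts, not a sample
from a larger one — with a `sample` (ddof=1) option. Since `sum(w) <= N`,
`sigma(w) <= sqrt(3)/4 * N`, so `0 <= pol(w) <= sqrt(3)/2 ~= 0.8660`, with
the maximum attained exactly by fully polarized edges `(S, 0, 0, 0)`
regardless of `S` and `N`.

The gene score divides the sum of incident-edge polarizations by `D`:

- `outer_norm="n_samples"` (default): `D = N`, the literal reading of the
  score's definition. R then grows with the number of polarized edges
  relative to the sample count; in dense networks high-degree genes are
  strongly favored, and a fixed threshold is implicitly scale-dependent.
- `outer_norm="degree"`: `D = degree(g)`, the mean edge polarization. R is
  then bounded by `sqrt(3)/2`, independent of network size, and a fixed
  threshold like 0.5 means "average edge more than ~58% of maximally
  polarized". This is the right choice for comparing runs of different sizes
  and is what the synthetic recovery analysis uses.

Both variants are computed from the same edge polarizations; every output
records which was used. A useful exact relation between them: duplicating
every sample doubles all weights and `N`, leaving each `pol(w)` unchanged
(`min/max` and `sigma/N` are scale-free), so the degree-normalized score is
invariant while the literal `1/N` score halves. Ranks are deterministic: ties
break lexicographically on gene identifier.

The OS/SO distinction needs an edge orientation; identifiers are compared
lexicographically and the smaller endpoint is "first". File formats state
this convention, and querying an edge from the other endpoint swaps wOS/wSO.

## Synthetic data

The generator emulates the data regime the method targets, not any specific
platform: background genes draw i.i.d. `Normal(0, background_sd)` log-ratios;
each planted module is active per sample with probability `p_on`, and in
active samples its members draw magnitudes `|Normal(mu_sig, sigma_sig)|` with
signs set by the pattern (OO all positive, SS all negative, OS half and
half); inactive samples fall back to background noise. Replicas are noisy
copies (background-sd jitter) sharing a spot-to-gene map. One master seed is
spawned into independent sub-streams per module plus one for the background
block, so adding a module never changes background draws.

Reference scenario (the defaults): `N = 20` samples, 200 background genes,
three 4-gene modules (one per pattern) with `p_on = 0.9`, `mu_sig = 2.0`,
`sigma_sig = 0.5`, `background_sd = 1.0`, one replica. The signal-to-noise
here is moderate — a 2-unit mean shift on unit-sd background — and the 90%
activity mirrors a mostly-consistent disease signature; `sigma_sig = 0.5`
adds biological variability to the planted amplitude without sign flips
being likely. At these settings all 12 planted genes typically outrank every
background gene under `outer_norm="degree"`.

What the generator does *not* emulate: dye bias, spatial artifacts,
heavy-tailed log-ratios, correlated background blocks, or realistic
gene-count scales. Passing the recovery tests therefore shows the scoring
machinery separates planted polarization from Gaussian background at
realistic sample counts; it does not certify performance on real microarray
data, where preprocessing quality dominates.

## Validation statistics

Filtered gene lists are validated against literature co-citation counts laid
out as a gene-group x disease contingency table. `chi_square_independence`
computes the Pearson statistic with expected counts from the marginals and
`df = (r-1)(c-1)`; no continuity correction by default (a flag enables Yates
for 2x2). P-values below double precision are floored at 1e-300 so "p <
0.0001"-style bound checks stay meaningful. Row/column percentages are
reported to two decimals; Bonferroni adjustment is `min(1, m*p)` with `m` at
least the list length. The shipped 3x3 citation table (157,780 citations)
gives statistic 64,897.4 with df = 4.

## Numerical and design choices

- **Identifier filtering before normalization.** When a spot-to-gene map is
  used, identifier handling happens before the per-sample moments are
  computed over whatever columns remain in the matrix.
- **Percent rendering.** Reduction ratios are rendered half-up to two
  decimals via `decimal.Decimal` (no binary-float rounding surprises), and
  the exact ratio is always emitted alongside, since truncation vs rounding
  conventions differ across publications.
- **Dense accumulation.** The builder iterates samples and enumerates pairs
  within each sample's expressed-gene set (cost `sum_i k_i^2`): expression
  networks are dense in expressed genes but samples are few, so this beats
  pairwise iteration over all `M^2` pairs.
- **Edge admission.** Any pair co-expressed in one sample gets an edge;
  weight sums therefore lie in `[1, N]` and equal the number of co-expressing
  samples (checked against a brute-force recount in the tests).
- **Degenerate inputs** are errors, not warnings: zero-variance samples,
  all-missing rows, non-positive intensities (named by cell), all-zero
  weight vectors, zero marginals in contingency tables, negative thresholds.

## Problem sizes

The test suite and the acceptance script run the reference scenario
(20 x 212 after planting, ~22k edges, ~1 s per build-and-score) over 10
seeds, 200 random oracle comparisons at `N <= 10`, `M <= 12`, and the
closed-form and citation-table checks, which are instantaneous. The
dataset-level results for the three public microarray series (39,028 -> 505
genes for AML, 7,531 -> 662 for BC, 6,826 -> 115 for DLCL at threshold 0.5)
are not recomputed here: they require downloading the GEO series, mapping
spots to Unigene identifiers, and replica handling whose exact parameters are
not fully documented; only the reduction-ratio arithmetic on the published
counts is verified. To attempt a reproduction: fetch the sample intensity
tables, take the two mean intensity channels as absolute expression, discard
spots without a valid gene identifier, apply steps 1-5 above with `eps = 0`,
the `any_replica` policy and threshold 0.5 under the literal `1/N`
normalization.

## Known limitations

- The literal `1/N` score is unbounded above and degree-driven in dense
  networks; prefer `outer_norm="degree"` for threshold transferability.
- Hard thresholding at `eps` ignores call uncertainty near the boundary;
  there is no per-gene variance model.
- Replica conflict resolution is heuristic; `max_magnitude` trusts single
  bright spots that may be artifacts.
- The chi-square validation treats citations as independent counts, which
  literature data are not; it is a consistency check, not an effect-size
  estimate.
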