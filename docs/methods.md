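# Methods

## Model and procedure

`dtwscore` quantifies, per gene, how differently that gene's expression
evolves over time across single cells, then uses the score for highly
variable gene selection and cell clustering.

1. **Quality filtering.** Only genes expressed — strictly positive in at
   least one time point — in at least 80% of cells are retained.
   "Expressed" carries no magnitude cutoff: FPKM values are
   length/depth-normalized, and a value of exactly 0 is the natural
   boundary between detected and undetected. The boundary is inclusive
   (a gene expressed in exactly 80% of cells is kept), the filter is
   idempotent, and the retained gene set is monotone in the threshold.

2. **DTW scoring.** For each gene and each cell pair, the expression
   series are aligned by dynamic time warping with scalar Euclidean local
   distance `d(m,n) = |x_m − x_n|` and the unweighted three-way recursion
   (diagonal, left, up steps all at weight 1), no warping-window
   constraint. The aligned cost `γ(n₁,n₂)` is divided by `n₁ + n₂` —
   path-length normalization that keeps alignments of unequal-length
   series comparable; that per-pair normalization is the only rescaling
   applied by default (an optional across-gene min–max rescale exists for
   exploration but changes nothing downstream since both the threshold
   model and ROC analysis are location/scale- and rank-based
   respectively). The DTWscore `D_i` is the arithmetic mean of the
   normalized distance over all unordered cell pairs, or over all
   cross-group pairs when two time periods are compared directly.

   Some DTW conventions pair the `(n₁+n₂)` normalization with a
   symmetric step pattern that double-weights the diagonal. Which
   convention a given analysis intends is not always decidable, so the
   unweighted recursion is the default and a `diagonal_weight=2.0` flag
   reproduces the weighted variant for cross-checks. The DTW distance is
   verified against an exhaustive enumeration of all monotone warping
   paths (an oracle guarded to `n₁·n₂ ≤ 64`).

3. **Threshold model.** Scores across genes are treated as draws from
   `N(μ, σ²)` with `μ` the sample mean and `σ²` the *population*
   (divisor-N) variance. The default selection rule is the conservative
   `μ + 4σ`; a normal-quantile rule `μ + z(q)·σ` (default q = 0.95) is
   the documented alternative. Selection is strict (`>`), so a
   degenerate fit with σ = 0 selects nothing. The model assumes the
   heterogeneous genes are a small minority; when they dominate the
   panel they inflate μ and σ and the 4-SD rule becomes very
   conservative (see the README example).

4. **Mixture clustering.** Cells (or pooled per-time observations) are
   clustered on the expression of the 1–3 top-scoring genes with a
   Gaussian mixture fitted by EM. Univariate fits use the two classical
   covariance structures — shared variance (`equal_variance`) and
   per-component variance (`free_variance`); multivariate fits use
   `diagonal` or `full`. Model selection minimizes
   `BIC = −2·loglik + p·log n` (note the sign: some ecosystems maximize
   the negation), with ties broken toward smaller K and then fewer free
   parameters.

5. **Evaluation.** ROC curves (one operating point per distinct score,
   trapezoidal AUC, which equals the Mann–Whitney pair statistic with
   half-credit for ties), sensitivity at fixed specificity read off the
   curve by linear interpolation, and percentile confidence intervals
   from a stratified bootstrap (positives and negatives resampled
   independently; 2000 replicates and 95% level by default). The
   percentile method was chosen over BCa as the simplest member of the
   family; intervals are clamped to bracket the full-data point
   estimate. Cluster labels are matched to truth labels by
   maximum-agreement assignment (Hungarian algorithm, exact) before
   computing accuracy.

## Synthetic data generator

The simulator emulates a two-period single-cell time course. Process
time t runs over an equally spaced, inclusive grid of 314 values from 0
to 10π, and four template trajectories are available:

| family | formula | noise |
|---|---|---|
| f1 | 5c·cos(t/5) + 8 + ε | yes |
| f2 | 5c·sin(t/5) + 8 + ε | yes |
| f3 | c·(t/10)² + ε + 5 | yes |
| f4 | 5·log(t+1) + 8 | none |

`c ~ N(1, 0.01)` is a trajectory coefficient drawn once per
(gene, cell) series — each series is its own biological instance of the
process — while `ε ~ N(0, σ²)` is observation noise drawn per time
point; σ defaults to 1.0. f4 is defined without noise terms and is kept
deterministic; a `noisy_f4` flag adds c and ε for symmetry experiments.
Negative values (possible in the noise tails) are clipped to 0 to stay
on the expression scale.

A dataset holds two cells, one per time period, and two gene groups:
500 non-heterogeneous genes (both cells drawn from the same template)
and 500 heterogeneous genes (one template per cell), by default. Each
cell's time points are subsampled from the grid once and shared across
genes — evenly spaced indices, or an uneven sorted draw without
replacement (the default, 30 points per cell; the two cells may use
different counts). Everything is reproducible from the config seed.

Six standard conditions fix the template pair: condition 1 = (f2, f3)
and condition 2 = (f2, f4); conditions 3–6 cover the remaining distinct
pairs (f1,f2), (f1,f3), (f1,f4), (f3,f4) by declared convention.

**What the simulator does not model:** dropout/zero-inflation, count
noise (the values are smooth functions plus Gaussian noise, not negative
binomial counts), more than two cells or groups, and cell-population
substructure. Passing tests on this generator therefore demonstrate that
the scoring machinery separates genuinely different temporal dynamics
from noise at the stated noise level — not that it is robust to the full
technical noise of real scRNA-seq.

## Numerical choices

- EM iterates to an absolute log-likelihood change below 1e-8 (max 500
  iterations); responsibilities are computed in log space with
  `logaddexp` for stability. Component (co)variances are floored at
  1e-10 × the total data variance so a component collapsing onto
  coincident points cannot blow up the likelihood. Initial covariances
  are projected onto the declared structure before the first E-step, so
  the per-iteration log-likelihood trace is non-decreasing from the
  start (a tested contract at tolerance 1e-9).
- Default EM initialization (`quantile_split`) sorts the data along the
  first dimension and cuts it into K equal-count blocks — deterministic
  given the data; `random` initialization takes an explicit seed.
- DTW traceback breaks ties diagonal-first, then left, then up, making
  the reported warping path deterministic.
- Hard mixture assignments break posterior ties toward the lowest
  component index.
- Uneven time subsampling uses a sorted draw without replacement so the
  per-cell grid is strictly increasing; even subsampling floors
  `linspace` indices (spacing ≥ 1 keeps them strictly increasing).
- Pseudo-series built by concatenating single-time observations within a
  group (`ordered_within_group`) are re-timed on an ordinal 0..n−1 grid:
  observations may share a time label (ties broken by cell id), and the
  ordinal grid keeps the strictly-increasing-times invariant.

## Problem sizes

The test suite and the reproduction script run the full study designs
where they are cheap (1000-gene simulations, 20-replicate calibrations,
n = 1000 mixture fits) and scaled-down replicas (60–120 genes) where a
shape check suffices; the acceptance script completes in well under a
minute on a single CPU.

## Known limitations

- The all-pairs score is O(genes × cell-pairs × n₁·n₂); it is meant for
  the post-filtering regime of hundreds of genes and short series, not
  for genome-wide scans over hundreds of cells.
- The normal threshold model is misspecified when heterogeneous genes
  are not a small minority of the panel (μ and σ absorb the signal).
- Only two covariance structures per dimensionality are implemented for
  the mixture; no non-Gaussian components, semi-supervised clustering or
  trajectory inference.
- How a multi-time series per cell is constructed from a design where
  each physical cell is captured once is genuinely ambiguous; both
  constructions (`per_cell_series`, `ordered_within_group`) are exposed
  and the choice is the user's.
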