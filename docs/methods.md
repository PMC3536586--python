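# Methods

## Model and pipeline

The package treats a gene-expression compendium as a genes × samples
matrix *V* of log-scale intensities and seeks a small set of *metagenes*
— nonnegative gene-loading vectors whose nonnegative linear combinations
reconstruct every sample. Formally *V ≈ W H* with *W* (genes × k) and
*H* (k × samples) elementwise nonnegative. Nonnegativity yields a
parts-based decomposition: genes contribute additively to metagenes, and
metagene activities add up to a sample's profile, which is what makes
individual columns of *W* interpretable as co-regulated gene groups.

The stages run in a fixed order: detection filter → row-mean centering →
L2-norm gene selection → empirical Bayes batch adjustment →
nonnegativity transform → NMF → metagene extraction → rank-based
statistics. Filtering precedes batch adjustment so that the EB priors
are estimated from informative genes only; nonnegativity is restored
last because centering and adjustment both produce negatives.

## Parameters that matter

| parameter | default | units / scale | why |
| --- | --- | --- | --- |
| detection threshold | 0.8 | fraction of samples | a gene absent/marginal in ≥ 80% of samples carries calls too unreliable to factor |
| top-N (L2 selection) | 7000 (clamped to matrix) | genes | keeps the highest-magnitude centered profiles; desk-scale runs clamp to the available genes |
| δ (coefficient cutoff) | 0.2 | raw *W* coefficient | genes below δ contribute negligibly to a metagene; applied to unnormalized coefficients |
| α (edge threshold) | 1e-12 | two-sided p-value | calibrated for compendium scale (hundreds of samples), where modest Spearman r gives astronomically small p; at n ≈ 60 it admits only near-perfect correlations |
| runs per k (consensus) | 50 (20 in desk-scale drivers) | NMF restarts | enough restarts for consensus entries (multiples of 1/runs) to resolve instability |
| NMF tol / max_outer | 1e-4 / 500 | relative projected-gradient norm | Lin-style stopping; consensus scans relax to 1e-3 / 200 since only the argmax clustering is consumed |
| EB convergence | 1e-6 / 100 iterations | parameter change | standard fixed-point hygiene for the posterior-mean equations |

## Numerical choices

**Projected-gradient ANLS.** Each subproblem min ½‖V − AX‖², X ≥ 0 is
solved by projected gradient with an Armijo search along the projection
arc (shrink factor β = 0.1, sufficient-decrease σ = 0.01, ≤ 20 step
trials), working from the Gram matrices A′A and A′V. Accepted steps
never increase the objective, so the outer objective trace is
nonincreasing. Initialization is Uniform(0, 1] scaled by √(mean(V)/k);
all-zero columns of W (or rows of H) arising mid-run are re-seeded with
uniform noise at 1e-6 of the initialization scale so dead metagenes can
re-enter the fit on degenerate inputs.

**Empirical Bayes batch adjustment.** The location/scale model
Y 〜 α + γ(batch) + δ(batch)·ε is standardized per gene by the pooled
within-batch variance; batch parameters are shrunk toward across-gene
moment-matched priors (normal for γ, inverse-gamma for δ²) via the
usual iterative posterior means. Degenerate inputs are handled by
flooring pooled variances and per-batch scale estimates at 1e-8, and by
skipping scale shrinkage when the across-gene variance of scale
estimates is ~0 (the inverse-gamma moment-matching divides by it). A
single batch has no contrast and is returned unchanged; a single-sample
batch gets its scale from the prior, with a warning.

**Cophenetic correlation.** Consensus dissimilarity is d = 1 − c̄ (the
only reading that yields a valid dissimilarity). Average linkage is
used for the hierarchical clustering; for a perfect 0/1 consensus the
cophenetic and original distances coincide, where an exact fast path
returns 1.0 (the moment formula would return 1 − 1e-16), and results
for perfect consensus matrices are linkage-invariant. Zero-variance
distance sets (e.g. an all-ones consensus) make the correlation
undefined; NaN is returned rather than raising.

**Rank-based statistics.** Mid-ranks are used for ties in both the
Kruskal–Wallis z-values and the Spearman correlations. The Spearman
edge p-value comes from the Student-t approximation with n − 2 degrees
of freedom; |r| = 1 is reported as t = ±∞ with p = 0. Hypergeometric
tail sums use log-gamma binomial coefficients and log-sum-exp, so
universes of thousands of genes neither overflow nor underflow. No
multiple-testing correction is applied anywhere — thresholds are on raw
p-values by design, and the number of tests performed is logged.

**Ties and determinism.** L2 selection and within-metagene gene ranking
break ties lexicographically by gene ID; the dominant-metagene
clustering breaks ties toward the smaller metagene index. Every
stochastic component takes an explicit seed, and child seeds fan out
from it by fixed offsets, so all results are bit-reproducible.

## The synthetic generator

The generator emulates a multi-series microarray compendium with known
ground truth: sparse exponential gene loadings (each gene loads on one
metagene, with probability 0.3 on a second), encoding rows with a
Uniform(0.1, 0.5) baseline multiplied by 4 in each series planted
active, per-batch per-gene additive shifts N(0, 0.5) with noise scale
factors in [0.8, 1.25] applied on the log-intensity scale, Gaussian
noise, and a planted fraction of genes carrying ≥ 80% "A" detection
calls. Samples fall into contiguous series blocks and round-robin
batches, so batch and series are not confounded.

What it does **not** emulate: probe-level artifacts, intensity-dependent
noise variance, correlated non-factor gene modules, or batch effects
shared across genes (each gene's shift is drawn independently).
Passing tests therefore show that the pipeline recovers planted
low-rank structure under location/scale batch effects and additive
noise — not that it is robust to the full pathology of real microarray
data.

## Design choices where the design was open

- **Nonnegativity after centering.** Centered (negative-containing)
  data must be made valid NMF input; two modes are provided. The
  package default is a global shift (subtract the matrix minimum),
  which preserves every pairwise difference. The analysis drivers use
  clip (negatives to zero) instead, because a global shift folds the
  baseline offset into every loading and makes the raw-coefficient
  δ = 0.2 cutoff vacuous — after clipping, loadings stay on the
  centered-intensity scale where δ bites. Neither mode is claimed to
  match the original analysis, which left this step unstated.
- **Batch adjustment runs after centering/selection**, following the
  stated stage order; running it on uncentered data would differ only
  in the location parameters the standardization removes anyway.
- **Rank choice is a report, not a decision.** The CCC-versus-k profile
  is emitted with its argmax, but the final k is a user judgment. On
  planted data the argmax is unreliable even when recovery is perfect:
  merges of true factors at small k are themselves highly reproducible
  (CCC ≈ 0.99 at k = 2 in several seeds), a known artifact of
  consensus-stability scans, and top-of-profile CCC differences are
  often < 0.003. Peaks followed by slow drop-off, inspected by eye,
  remain the operative heuristic.
- **KW z-values use raw encoding rows**; the statistic is rank-based,
  so any strictly monotone per-row normalization gives identical
  results.
- **Overlap background** defaults to the filtered gene universe;
  cluster genes outside it are excluded from the counts (with a
  warning) so all four hypergeometric arguments refer to the same
  universe.

## Problem sizes

The desk-scale study the tests and drivers run is 200 genes × 60
samples with 4 planted metagenes, 3 batches, noise sd 0.1; consensus
scans use k = 2…8 with 20 restarts per k. These sizes were chosen so a
full validation pass completes in minutes on a single core while still
exercising every stage at nontrivial scale; the algorithms themselves
are dense-matrix and comfortably handle compendium scale (thousands of
genes × hundreds of samples).

## Known limitations

- Consensus-scan rank recovery by global CCC argmax is unreliable at
  desk scale (see above); the profile should be inspected.
- The EB corrector is parametric-only: no nonparametric variant, no
  reference batch, and no covariate preservation, so biological
  contrasts confounded with batch are removed along with the batch
  effect.
- The Spearman edge threshold α = 10⁻¹² presumes hundreds of samples;
  with tens of samples the network is empty and a desk-scale threshold
  must be chosen deliberately.
- The correlation diagnostic detects batch structure shared across
  genes; fully gene-independent batch shifts leave its signed average
  near zero (they cancel in expectation) even though they are present
  and correctable.
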