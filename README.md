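# metanmf

Metagene discovery from gene-expression compendia by non-negative matrix
factorization, for transcriptomics researchers who want the full
workflow — filtering, batch correction, factorization, rank selection,
and metagene characterization — as a tested, reproducible Python library
rather than a chain of one-off scripts.

## The method

Given a genes × samples expression matrix *V* (log-scale intensities),
the pipeline:

1. **Filters** genes called absent/marginal in ≥ 80% of samples,
   subtracts each gene's mean, and keeps the top genes by L2 norm
   ‖g‖₂ = √(g₁² + ⋯ + g_P²).
2. **Adjusts batch effects** with a parametric empirical Bayes
   location/scale model: per-gene batch shifts and scale factors are
   estimated, shrunk toward across-gene priors (normal / inverse-gamma),
   and removed. A random-gene-pair correlation diagnostic checks the
   correction.
3. **Factorizes** *V ≈ W H* with *W* ≥ 0 (genes × k metagene loadings)
   and *H* ≥ 0 (k × samples encoding coefficients), by alternating
   nonnegative least squares with projected-gradient subproblem solves
   (Armijo search along the projection arc).
4. **Selects the rank k** by consensus clustering: over many seeded
   runs, samples are clustered by their dominant metagene
   (argmaxᵢ *h*ᵢⱼ), connectivity matrices are averaged into a consensus
   matrix, and its cophenetic correlation coefficient (CCC) scores the
   stability of each candidate k.
5. **Extracts metagenes**: *W* columns are ordered by activity (column
   sum) and thresholded at δ = 0.2; ranked gene lists are exported as
   RNK/GMT for preranked enrichment tools.
6. **Characterizes metagenes** by (a) per-series Kruskal–Wallis
   z-values *z*ⱼ = (R̄ⱼ − R̄) / √((N+1)(N/Nⱼ − 1)/12) on the ranked
   encoding rows, (b) a Spearman correlation network over encoding rows
   with edges at p < α = 10⁻¹² (Student-t approximation,
   t = r√(n−2)/√(1−r²), n−2 df), and (c) hypergeometric overlap
   p-values against external gene-cluster collections, computed in log
   space.

A synthetic-data generator plants known factor structure (sparse
exponential loadings, series-structured encodings, batch location/scale
effects, absent-gene detection calls) so every stage can be validated
against ground truth.

## Worked example

The `analysis/` scripts run the whole study at desk scale (200 genes ×
60 samples, four planted metagenes, three batches):

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_batch_correct.py
python analysis/04_rank_scan.py
python analysis/05_factorize_extract.py
python analysis/06_series_activity.py
python analysis/07_network_overlap.py
```

Step 03 reports the batch correction:

```
between-batch gene-mean spread: 0.6116 -> 0.0337 (94.5% reduction)
```

meaning the planted per-gene batch shifts are almost entirely removed.
Step 04 prints the CCC-versus-k profile (here peaking at the planted
rank, k = 4), and step 05 the fit and recovery:

```
factorized 150x60 at k=4: 10 outer iterations, relative error 0.0908
metagene sizes at delta=0.2: [47, 46, 50, 34]
matched cosine similarity to planted loadings: [0.996, 0.994, 0.997, 0.997]
```

i.e. each fitted metagene matches a planted loading vector almost
perfectly after Hungarian matching. Step 06 shows each metagene's
Kruskal–Wallis z-value peaking in its planted series (z ≈ +5.7,
negative elsewhere), and step 07 the overlap heatmap, whose matched
metagene–cluster cells reach log₁₀ p ≈ −12 to −15 while all other cells
sit near 0.

The same workflow is available programmatically:

```python
from metanmf.pipeline import PipelineConfig, run_pipeline
artifacts = run_pipeline(PipelineConfig(outdir="results/run", seed=1))
```

which writes every table (expression, CCC profile, metagene lists,
activity z-values, network SIF/edge attributes, overlap p-values) plus a
manifest with parameters, seeds and file hashes.

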