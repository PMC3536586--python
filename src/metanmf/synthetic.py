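"""Synthetic expression data with planted metagene structure.

Generates a gene x sample matrix ``V = W_true @ H_true + batch effects +
noise`` so every downstream stage (filtering, batch adjustment, NMF rank
selection, metagene statistics) can be checked against known ground
truth.  The design mimics a multi-series microarray compendium: samples
fall into experimental series, a planted subset of metagenes is elevated
in each series, batches shift gene locations and inflate noise scales on
the log-intensity scale, and a planted fraction of genes carries "absent"
detection calls.

What it deliberately does not emulate: probe-level artifacts, intensity-
dependent noise, or correlated (non-factor) gene modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.optimize import linear_sum_assignment

__all__ = [
    "SyntheticTruth",
    "generate_dataset",
    "derive_cluster_sets",
    "match_columns",
]

# Study-condition constants (fixed design, not tuning knobs): sparse
# exponential gene loadings, a uniform(0.1, 0.5) baseline encoding with
# planted-active series rows multiplied by 4, batch shifts N(0, 0.5) and
# batch scale factors in [0.8, 1.25] on the log-intensity scale.
_LOADING_SCALE = 1.0
_LOADING_OFFSET = 0.5
_SECOND_LOADING_PROB = 0.3
_H_BASE_LOW, _H_BASE_HIGH = 0.1, 0.5
_ACTIVE_MULTIPLIER = 4.0
_BATCH_SHIFT_SD = 0.5
_BATCH_SCALE_LOW, _BATCH_SCALE_HIGH = 0.8, 1.25
_ABSENT_CALL_RATE = 0.9

# One global seed fans out to per-component child seeds by fixed offsets.
_SEED_MOD = 2**31
_OFFSETS = {"W": 1, "H": 2, "batch": 3, "noise": 4, "calls": 5, "clusters": 6}


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    W_true: np.ndarray
    H_true: np.ndarray
    batch_shift: np.ndarray  # (n_batches, n_genes) additive offsets
    batch_scale: np.ndarray  # (n_batches, n_genes) noise scale factors, > 0
    noise_sd: float
    absent_genes: frozenset
    series_design: dict  # series label -> set of planted-active metagene indices
    seed: int
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    @property
    def k_true(self) -> int:
        return self.W_true.shape[1]


def _child_rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng((seed + _OFFSETS[component]) % _SEED_MOD)


def _default_series_design(k_true: int) -> dict:
    # One series per planted metagene: series i activates metagene i.
    return {f"series_{i + 1}": {i} for i in range(k_true)}


def generate_dataset(
    n_genes: int,
    n_samples: int,
    k_true: int,
    n_batches: int = 1,
    series_design: dict | None = None,
    noise_sd: float = 0.1,
    absent_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate an expression matrix with planted factor structure.

    Returns ``(expression, detection_calls, sample_annotation, truth)``.
    Expression and calls are genes x samples DataFrames; the annotation
    maps each sample to its batch and series.  Samples are assigned to
    series in contiguous blocks (as in a multi-experiment compendium) and
    to batches round-robin, so batch and series are not confounded.

    With ``n_batches=1`` no batch effects are applied; with
    ``noise_sd=0`` and ``absent_fraction=0`` as well, the matrix equals
    ``W_true @ H_true`` exactly.
    """
    if not 1 <= k_true < min(n_genes, n_samples):
        raise ValueError(f"k_true={k_true} must satisfy 1 <= k_true < min{(n_genes, n_samples)}")
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if not 0 <= absent_fraction < 1:
        raise ValueError("absent_fraction must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if series_design is None:
        series_design = _default_series_design(k_true)
    for s, mset in series_design.items():
        bad = [m for m in mset if not 0 <= m < k_true]
        if bad:
            raise ValueError(f"series {s!r} references metagene indices {bad} outside [0, {k_true})")

    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"s{j + 1:04d}" for j in range(n_samples)]

    # Sparse exponential loadings: each gene loads strongly on one
    # metagene, sometimes a second, and is exactly zero elsewhere.
    rng_w = _child_rng(seed, "W")
    W = np.zeros((n_genes, k_true))
    primary = rng_w.integers(0, k_true, size=n_genes)
    W[np.arange(n_genes), primary] = rng_w.exponential(_LOADING_SCALE, n_genes) + _LOADING_OFFSET
    second_mask = rng_w.random(n_genes) < _SECOND_LOADING_PROB
    secondary = (primary + rng_w.integers(1, k_true, size=n_genes)) % k_true if k_true > 1 else primary
    rows = np.flatnonzero(second_mask)
    if k_true > 1 and len(rows):
        W[rows, secondary[rows]] = rng_w.exponential(_LOADING_SCALE / 2, len(rows))

    # Series in contiguous blocks, batches round-robin.
    series_labels = list(series_design)
    bounds = np.linspace(0, n_samples, len(series_labels) + 1).astype(int)
    series_of = np.empty(n_samples, dtype=object)
    for i, lab in enumerate(series_labels):
        series_of[bounds[i]:bounds[i + 1]] = lab
    batch_of = np.array([f"batch_{(j % n_batches) + 1}" for j in range(n_samples)])

    rng_h = _child_rng(seed, "H")
    H = rng_h.uniform(_H_BASE_LOW, _H_BASE_HIGH, size=(k_true, n_samples))
    for lab, metagenes in series_design.items():
        cols = np.flatnonzero(series_of == lab)
        for m in metagenes:
            H[m, cols] *= _ACTIVE_MULTIPLIER

    V = W @ H

    rng_b = _child_rng(seed, "batch")
    if n_batches > 1:
        batch_shift = rng_b.normal(0.0, _BATCH_SHIFT_SD, size=(n_batches, n_genes))
        batch_scale = rng_b.uniform(_BATCH_SCALE_LOW, _BATCH_SCALE_HIGH, size=(n_batches, n_genes))
    else:
        batch_shift = np.zeros((1, n_genes))
        batch_scale = np.ones((1, n_genes))

    rng_n = _child_rng(seed, "noise")
    noise = rng_n.normal(0.0, noise_sd, size=V.shape) if noise_sd > 0 else np.zeros_like(V)
    batch_idx = np.array([j % n_batches for j in range(n_samples)])
    V = V + batch_shift[batch_idx].T + batch_scale[batch_idx].T * noise

    # Detection calls: planted-absent genes get "A" in ~90% of samples,
    # everything else is called present.
    rng_c = _child_rng(seed, "calls")
    n_absent = int(round(absent_fraction * n_genes))
    absent_rows = rng_c.choice(n_genes, size=n_absent, replace=False) if n_absent else np.array([], int)
    calls = np.full((n_genes, n_samples), "P", dtype=object)
    for r in absent_rows:
        mask = rng_c.random(n_samples) < _ABSENT_CALL_RATE
        while mask.mean() < 0.8:  # guarantee the planted gene fails the 80% filter
            mask[rng_c.integers(0, n_samples)] = True
        calls[r, mask] = "A"

    expr = pd.DataFrame(V, index=gene_ids, columns=sample_ids)
    calls_df = pd.DataFrame(calls, index=gene_ids, columns=sample_ids)
    ann = pd.DataFrame({"batch": batch_of, "series": series_of},
                       index=pd.Index(sample_ids, name="sample_id"))
    truth = SyntheticTruth(
        W_true=W,
        H_true=H,
        batch_shift=batch_shift,
        batch_scale=batch_scale,
        noise_sd=noise_sd,
        absent_genes=frozenset(gene_ids[r] for r in absent_rows),
        series_design={s: set(m) for s, m in series_design.items()},
        seed=seed,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )
    return expr, calls_df, ann, truth


def derive_cluster_sets(
    truth: SyntheticTruth, top_m: int, jitter: float = 0.0, seed: int = 0
) -> dict:
    """External-style gene clusters derived from the planted loadings.

    Cluster c holds the ``top_m`` genes with the largest loading on
    planted metagene c; a ``jitter`` fraction of each cluster is replaced
    by random genes from outside it.  With ``jitter=0`` the clusters are
    exactly the planted top loadings; with ``jitter=1`` they are random
    gene sets.  Returns ``{cluster_name: list of gene IDs}`` suitable for
    GMT export.
    """
    if truth.W_true.size == 0 or not truth.gene_ids:
        raise ValueError("truth carries no genes")
    n_genes = truth.W_true.shape[0]
    if not 1 <= top_m <= n_genes:
        raise ValueError(f"top_m={top_m} must be in [1, {n_genes}]")
    if not 0 <= jitter <= 1:
        raise ValueError("jitter must be in [0, 1]")
    rng = _child_rng(seed, "clusters")
    gene_ids = np.asarray(truth.gene_ids)
    clusters = {}
    for c in range(truth.k_true):
        # stable top-m: sort by (-loading, gene id)
        loading = truth.W_true[:, c]
        order = np.lexsort((gene_ids, -loading))
        members = list(gene_ids[order[:top_m]])
        n_replace = int(round(jitter * top_m))
        if n_replace:
            outside = np.setdiff1d(gene_ids, members)
            keep_idx = rng.choice(top_m, size=top_m - n_replace, replace=False)
            kept = [members[i] for i in sorted(keep_idx)]
            extra = list(rng.choice(outside, size=min(n_replace, len(outside)), replace=False))
            members = kept + extra
        clusters[f"cluster_{c + 1}"] = members
    return clusters


def match_columns(W: np.ndarray, W_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match columns of ``W`` to ``W_ref`` by maximum-cosine assignment.

    Uses the Hungarian algorithm on the pairwise cosine-similarity matrix.
    Returns ``(permutation, cosines)`` where ``permutation[j]`` is the
    column of ``W`` matched to column j of ``W_ref`` and ``cosines[j]``
    the achieved similarity.
    """
    W = np.asarray(W, float)
    W_ref = np.asarray(W_ref, float)
    if W.shape != W_ref.shape:
        raise ValueError("shape mismatch")
    norm = lambda M: M / np.maximum(np.linalg.norm(M, axis=0, keepdims=True), 1e-12)
    S = norm(W_ref).T @ norm(W)  # S[j, i] = cos(ref_j, W_i)
    rows, cols = linear_sum_assignment(-S)
    return cols, S[rows, cols]
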