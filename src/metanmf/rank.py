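"""Rank selection for NMF by consensus-clustering stability.

Each NMF run clusters samples by their dominant metagene (the argmax of
each column of H).  Over many seeded runs at a candidate rank k, the
binary connectivity matrices are averaged into a consensus matrix whose
entries estimate the probability that two samples co-cluster.  The
cophenetic correlation coefficient (CCC) of the consensus matrix scores
the stability of k: 1 for a perfectly reproducible clustering, lower as
co-clustering probabilities disperse between 0 and 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .nmf import factorize

__all__ = [
    "ConsensusResult",
    "cluster_samples",
    "connectivity",
    "consensus",
    "cophenetic_coefficient",
    "scan_ranks",
]

_SEED_MOD = 2**31


@dataclass
class ConsensusResult:
    """Consensus matrix and stability score for one candidate rank.

    ``ccc`` is NaN when the cophenetic correlation is undefined (all
    pairwise consensus distances identical, e.g. a single all-ones block).
    """

    k: int
    consensus: np.ndarray
    ccc: float
    n_runs: int


def cluster_samples(H: np.ndarray) -> np.ndarray:
    """Assign each sample (column of H) to its most active metagene.

    Sample j goes to cluster ``argmax_i H[i, j]``; ties break to the
    smallest row index.  Returns an int array of length n_samples.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.size == 0:
        raise ValueError("H must be a nonempty 2-D matrix")
    return np.argmax(H, axis=0)


def connectivity(assignment: np.ndarray) -> np.ndarray:
    """Binary co-membership matrix: 1 where two samples share a cluster."""
    a = np.asarray(assignment)
    return (a[:, None] == a[None, :]).astype(np.int8)


def consensus(connectivities: list, k: int | None = None) -> ConsensusResult:
    """Elementwise mean of connectivity matrices (the consensus matrix).

    The CCC field is left NaN; use :func:`cophenetic_coefficient` (or
    :func:`scan_ranks`, which fills it) to score stability.
    """
    if len(connectivities) == 0:
        raise ValueError("need at least one connectivity matrix")
    shape = np.asarray(connectivities[0]).shape
    for i, c in enumerate(connectivities):
        if np.asarray(c).shape != shape:
            raise ValueError(f"connectivity matrix {i} has shape {np.asarray(c).shape}, expected {shape}")
    mean = np.mean([np.asarray(c, dtype=float) for c in connectivities], axis=0)
    return ConsensusResult(k=k if k is not None else -1, consensus=mean,
                           ccc=math.nan, n_runs=len(connectivities))


def cophenetic_coefficient(consensus_matrix: np.ndarray) -> float:
    """Cophenetic correlation of a consensus matrix.

    Samples are clustered hierarchically (average linkage) on the
    dissimilarity ``d_ij = 1 - c_ij``; the CCC is the Pearson correlation
    between the cophenetic distances of that tree and the original
    dissimilarities.  Returns NaN when either distance set has zero
    variance (the correlation is undefined, not an error).
    """
    C = np.asarray(consensus_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] < 2:
        raise ValueError("consensus must be a square matrix with >= 2 samples")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    original = squareform(D, checks=False)
    Z = linkage(original, method="average")
    coph = cophenet(Z)
    if np.ptp(original) == 0.0 or np.ptp(coph) == 0.0:
        return math.nan
    if np.array_equal(original, coph):
        # identical distance sets (e.g. a perfect 0/1 consensus) correlate
        # perfectly; bypass floating-point round-off in the moment formula
        return 1.0
    # Pearson correlation; both vectors have nonzero variance here.
    return float(np.corrcoef(original, coph)[0, 1])


def scan_ranks(
    V: np.ndarray,
    k_values,
    runs_per_k: int = 50,
    seed: int = 0,
    tol: float = 1e-3,
    max_outer: int = 200,
) -> list[ConsensusResult]:
    """Consensus-stability scan over candidate ranks.

    For each k, runs ``runs_per_k`` seeded factorizations, clusters
    samples by dominant metagene, averages the connectivity matrices and
    scores the consensus with the CCC.  Per-run seeds are derived from
    ``seed`` by fixed offsets, so the full profile is reproducible.

    The per-run factorizations use relaxed convergence settings (the
    cluster assignments, not the exact optimum, are what is averaged);
    tighten ``tol``/``max_outer`` for publication-grade scans.
    """
    V = np.asarray(V, dtype=float)
    n, p = V.shape
    results = []
    for k in k_values:
        if not 1 <= k < min(n, p):
            raise ValueError(f"k={k} must satisfy 1 <= k < min{(n, p)}")
        conns = []
        for run in range(runs_per_k):
            run_seed = (seed + 10_000 * k + run) % _SEED_MOD
            fact = factorize(V, k, seed=run_seed, tol=tol, max_outer=max_outer)
            conns.append(connectivity(cluster_samples(fact.H)))
        res = consensus(conns, k=k)
        res.ccc = cophenetic_coefficient(res.consensus)
        results.append(res)
    return results
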