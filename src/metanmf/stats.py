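"""Metagene characterization statistics.

Three rank-based procedures describe what the fitted metagenes do:

* **Series activity** — for each metagene, the per-series Kruskal-Wallis
  z-value ``z_j = (Rbar_j - Rbar) / sqrt((N+1) (N/N_j - 1) / 12)``
  computed on the ranks of its encoding row.  Positive z means the
  metagene is elevated in series j, negative that it is suppressed.
* **Correlation network** — pairwise Spearman correlation between
  encoding rows; the p-value comes from the Student-t approximation
  ``t = r sqrt(n-2) / sqrt(1 - r^2)`` with n-2 degrees of freedom, and an
  edge is drawn when p < alpha (default 1e-12).
* **Cluster overlap** — upper-tail hypergeometric p-value for the
  intersection of a metagene's gene list with an external gene cluster
  within a background universe of N genes, evaluated in log space.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata, t as t_dist

__all__ = [
    "ActivityMatrix",
    "CorrelationNetwork",
    "OverlapMatrix",
    "kw_zvalues",
    "activity_matrix",
    "build_network",
    "hypergeom_p",
    "overlap_heatmap",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- activity

@dataclass
class ActivityMatrix:
    """Metagene x series matrix of Kruskal-Wallis z-values."""

    z: pd.DataFrame  # rows: metagene_1.. ; columns: series labels
    series_labels: list


def kw_zvalues(h_row: np.ndarray, groups) -> pd.Series:
    """Kruskal-Wallis group z-values for one encoding row.

    Activation levels are ranked across all N samples (mid-ranks for
    ties); each group's z-value standardizes the deviation of its mean
    rank from the grand mean rank ``(N+1)/2``.  Being rank-based, the
    result is invariant to any strictly monotone transform of the row.
    """
    x = np.asarray(h_row, dtype=float)
    groups = np.asarray(groups)
    if x.ndim != 1 or len(groups) != len(x):
        raise ValueError("h_row and groups must be aligned 1-D sequences")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    N = len(x)
    ranks = rankdata(x)
    grand = ranks.mean()
    out = {}
    for lab in labels:
        mask = groups == lab
        n_j = int(mask.sum())
        if n_j == 0:
            raise ValueError(f"group {lab!r} is empty")
        if n_j == N:
            raise ValueError(f"group {lab!r} contains every sample; z undefined")
        se = math.sqrt((N + 1) * (N / n_j - 1) / 12.0)
        out[lab] = (ranks[mask].mean() - grand) / se
    return pd.Series(out, name="z")


def activity_matrix(H: np.ndarray, groups, metagene_names=None) -> ActivityMatrix:
    """Kruskal-Wallis z-values for every encoding row of H."""
    H = np.asarray(H, dtype=float)
    rows = []
    for i in range(H.shape[0]):
        rows.append(kw_zvalues(H[i], groups))
    names = metagene_names or [f"metagene_{i + 1}" for i in range(H.shape[0])]
    z = pd.DataFrame(rows, index=names)
    return ActivityMatrix(z=z, series_labels=list(z.columns))


# ----------------------------------------------------------------- network

@dataclass
class CorrelationNetwork:
    """Spearman correlation network over metagene encoding rows.

    Edges are stored once per unordered pair (i < j) with the Spearman
    correlation r, the t statistic (inf for |r| = 1), the two-sided
    p-value and the sign of r.  Node activity (W column sums) sizes the
    nodes in downstream rendering.
    """

    edges: pd.DataFrame  # columns: source, target, r, t, p, sign
    alpha: float
    n_samples: int
    df: int
    activity: np.ndarray | None = None
    n_tests: int = 0
    node_names: list = field(default_factory=list)

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph(alpha=self.alpha, df=self.df)
        for i, name in enumerate(self.node_names):
            attrs = {}
            if self.activity is not None:
                attrs["activity"] = float(self.activity[i])
            G.add_node(name, **attrs)
        for row in self.edges.itertuples(index=False):
            G.add_edge(row.source, row.target, r=row.r, t=row.t, p=row.p, sign=row.sign)
        return G


def spearman_edge_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Spearman r with the Student-t approximation to its p-value.

    Returns ``(r, t, p)`` where ``t = r sqrt(n-2)/sqrt(1-r^2)`` follows a
    Student-t with n-2 degrees of freedom under the null; p is two-sided.
    For |r| = 1 the statistic is unbounded: t is +/-inf and p is 0.
    """
    rx, ry = rankdata(x), rankdata(y)
    n = len(rx)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        return math.copysign(1.0, r), math.copysign(math.inf, r), 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, t, min(p, 1.0)


def build_network(
    H: np.ndarray,
    alpha: float = 1e-12,
    activity: np.ndarray | None = None,
    node_names=None,
) -> CorrelationNetwork:
    """Threshold pairwise Spearman correlations of encoding rows into edges.

    An edge joins metagenes i and j when the two-sided Student-t p-value
    of their Spearman correlation is below ``alpha``.  Constant rows have
    undefined correlations; their pairs are skipped with a warning.
    """
    H = np.asarray(H, dtype=float)
    k, n = H.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if k < 2:
        raise ValueError("need at least 2 metagenes")
    names = list(node_names) if node_names is not None else [f"metagene_{i + 1}" for i in range(k)]
    constant = np.ptp(H, axis=1) == 0
    records = []
    n_tests = 0
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                warnings.warn(f"constant encoding row: skipping pair ({names[i]}, {names[j]})")
                continue
            n_tests += 1
            r, t, p = spearman_edge_test(H[i], H[j])
            if p < alpha:
                records.append(
                    {"source": names[i], "target": names[j], "r": r, "t": t,
                     "p": p, "sign": 1 if r > 0 else -1}
                )
    log.info("correlation network: %d pairs tested, %d edges at alpha=%g (no multiplicity correction)",
             n_tests, len(records), alpha)
    edges = pd.DataFrame(records, columns=["source", "target", "r", "t", "p", "sign"])
    return CorrelationNetwork(
        edges=edges, alpha=alpha, n_samples=n, df=n - 2,
        activity=None if activity is None else np.asarray(activity, float),
        n_tests=n_tests, node_names=names,
    )


# ----------------------------------------------------------------- overlap

def hypergeom_p(x: int, ms: int, cs: int, N: int) -> float:
    """Upper-tail hypergeometric overlap p-value.

    Probability of at least ``x`` shared genes between a metagene of size
    ``ms`` and a cluster of size ``cs`` drawn from a background of ``N``
    genes: ``sum_{i=x}^{min(ms,cs)} C(ms,i) C(N-ms,cs-i) / C(N,cs)``.
    Binomial coefficients are evaluated through log-gamma so universes of
    thousands of genes do not overflow.
    """
    for name, v in (("x", x), ("ms", ms), ("cs", cs), ("N", N)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    if ms > N or cs > N:
        raise ValueError(f"set sizes (ms={ms}, cs={cs}) cannot exceed the background N={N}")
    upper = min(ms, cs)
    if x > upper:
        raise ValueError(f"overlap x={x} exceeds min(ms, cs)={upper}")
    if x == 0:
        return 1.0

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    i = np.arange(x, upper + 1)
    valid = cs - i <= N - ms  # terms with impossible complements vanish
    i = i[valid]
    if len(i) == 0:
        return 0.0
    log_terms = log_comb(ms, i) + log_comb(N - ms, cs - i) - log_comb(N, cs)
    return float(min(1.0, math.exp(logsumexp(log_terms))))


@dataclass
class OverlapMatrix:
    """Hypergeometric overlap p-values between metagenes and clusters."""

    p: pd.DataFrame
    log10_p: pd.DataFrame
    row_order: list
    col_order: list
    background_n: int


def overlap_heatmap(metagene_sets: dict, clusters: dict, background) -> OverlapMatrix:
    """All-pairs overlap p-values plus dendrogram display orders.

    ``metagene_sets`` and ``clusters`` map names to gene collections;
    ``background`` is the gene universe (its size is the hypergeometric
    N).  Cluster or metagene genes outside the universe are dropped with
    a warning, so every count is taken within the background.  Rows and
    columns are ordered by average-linkage hierarchical clustering on the
    Euclidean distance of the log10 p-value profiles.
    """
    universe = set(map(str, background))
    N = len(universe)
    if N == 0:
        raise ValueError("empty background universe")

    def restrict(named_sets, kind):
        out = {}
        for name, genes in named_sets.items():
            genes = set(map(str, genes))
            dropped = genes - universe
            if dropped:
                warnings.warn(
                    f"{kind} {name!r}: {len(dropped)} gene(s) outside the background excluded"
                )
            out[name] = genes & universe
        return out

    mg = restrict(metagene_sets, "metagene")
    cl = restrict(clusters, "cluster")
    p = pd.DataFrame(index=list(mg), columns=list(cl), dtype=float)
    for mname, mgenes in mg.items():
        for cname, cgenes in cl.items():
            x = len(mgenes & cgenes)
            p.loc[mname, cname] = hypergeom_p(x, len(mgenes), len(cgenes), N)
    log.info("overlap heatmap: %d hypergeometric tests (no multiplicity correction)", p.size)
    log10_p = np.log10(p)

    def display_order(M):
        if M.shape[0] < 2:
            return list(M.index)
        d = pdist(M.to_numpy(), metric="euclidean")
        return [M.index[i] for i in leaves_list(linkage(d, method="average"))]

    return OverlapMatrix(
        p=p,
        log10_p=log10_p,
        row_order=display_order(log10_p),
        col_order=display_order(log10_p.T),
        background_n=N,
    )
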