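"""Metagene ordering, gene ranking, and coefficient thresholding.

After factorization the columns of W are sorted by total activity (column
sum), the rows of H are permuted identically so reconstruction is
unchanged, and each metagene keeps the genes whose loading exceeds the
cutoff ``delta`` (default 0.2), ranked by descending coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nmf import Factorization

__all__ = ["MetageneSet", "order_and_extract", "export_ranked_lists"]


@dataclass
class MetageneSet:
    """Activity-ordered, delta-thresholded metagenes.

    ``metagenes[c]`` is the list of ``(gene_id, coefficient)`` pairs with
    coefficient > delta, sorted descending (ties lexicographic by ID).
    ``W``/``H`` are the permuted factor matrices; ``order`` maps each
    output position to the original column index.  A gene may appear in
    several metagenes.
    """

    metagenes: list
    delta: float
    activity: np.ndarray
    order: np.ndarray
    W: np.ndarray
    H: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def gene_sets(self) -> dict:
        """Thresholded gene lists keyed ``metagene_1`` (most active) on."""
        return {
            f"metagene_{c + 1}": [g for g, _ in genes]
            for c, genes in enumerate(self.metagenes)
        }


def order_and_extract(
    fact: Factorization,
    delta: float = 0.2,
    gene_ids: list | None = None,
    sample_ids: list | None = None,
) -> MetageneSet:
    """Sort metagenes by activity and apply the coefficient cutoff.

    Activity is the column sum of W; columns (and the matching rows of H)
    are permuted into descending-activity order, so metagene 1 is the
    most active.  Within each metagene, genes with coefficient strictly
    greater than ``delta`` are kept, in descending-coefficient order.  An
    all-below-threshold column yields an empty metagene that keeps its
    rank position (with a warning).
    """
    if delta < 0:
        raise ValueError(f"delta must be nonnegative, got {delta}")
    W, H = fact.W, fact.H
    n_genes, k = W.shape
    if gene_ids is None:
        gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"s{j + 1:04d}" for j in range(H.shape[1])]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length does not match W")

    sums = W.sum(axis=0)
    order = np.argsort(-sums, kind="stable")
    W_ord = W[:, order]
    H_ord = H[order, :]

    ids = np.asarray(gene_ids, dtype=object)
    metagenes = []
    for c in range(k):
        col = W_ord[:, c]
        keep = np.flatnonzero(col > delta)
        ranked = sorted(
            ((str(ids[i]), float(col[i])) for i in keep),
            key=lambda t: (-t[1], t[0]),
        )
        if not ranked:
            warnings.warn(f"metagene {c + 1} is empty at delta={delta}")
        metagenes.append(ranked)

    return MetageneSet(
        metagenes=metagenes,
        delta=delta,
        activity=sums[order],
        order=order,
        W=W_ord,
        H=H_ord,
        gene_ids=list(map(str, gene_ids)),
        sample_ids=list(map(str, sample_ids)),
    )


def export_ranked_lists(ms: MetageneSet, outdir: str | Path) -> dict:
    """Write one RNK file per metagene and a GMT of the thresholded sets.

    Each RNK ranks *all* genes by their loading on that metagene
    (descending), ready for preranked gene-set enrichment tools; the GMT
    holds the delta-thresholded member lists.  Returns the written paths.
    """
    if not ms.metagenes:
        raise ValueError("empty MetageneSet")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"rnk": [], "gmt": None}
        ids = np.asarray(ms.gene_ids, dtype=object)
        for c in range(ms.W.shape[1]):
            col = ms.W[:, c]
            order = sorted(range(len(ids)), key=lambda i: (-col[i], str(ids[i])))
            path = outdir / f"metagene_{c + 1}.rnk"
            with open(path, "w") as fh:
                for i in order:
                    fh.write(f"{ids[i]}\t{col[i]:.10g}\n")
            paths["rnk"].append(path)
        gmt_path = outdir / "metagenes.gmt"
        with open(gmt_path, "w") as fh:
            for name, genes in ms.gene_sets().items():
                fh.write("\t".join([name, f"delta>{ms.delta}"] + genes) + "\n")
        paths["gmt"] = gmt_path
        return paths
    except OSError as e:
        raise OSError(f"failed writing metagene exports under {outdir}: {e}") from e
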