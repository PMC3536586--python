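"""Expression-matrix filtering and NMF input preparation.

Matrices are pandas DataFrames: genes on the index, samples on the
columns, log-scale intensities.  The pipeline order is detection filter
-> row-mean centering -> L2-norm gene selection -> (batch adjustment) ->
nonnegativity transform.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["detection_filter", "center_genes", "l2_select", "to_nonnegative"]

log = logging.getLogger(__name__)

#: detection-call codes: present / marginal / absent
CALL_CODES = ("P", "M", "A")


def detection_filter(
    expr: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    threshold: float = 0.8,
    proxy_quantile: float = 0.25,
) -> pd.DataFrame:
    """Drop genes undetected in most samples.

    A gene is removed when the fraction of its detection calls that are
    absent ("A") or marginal ("M") is at least ``threshold`` (default
    80%).  Gene order is preserved.

    When no call matrix is available, an expression-proxy rule is used
    instead: a gene is retained if at least ``1 - threshold`` of its
    samples exceed the global ``proxy_quantile`` intensity quantile.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if calls is None:
        log.warning(
            "no detection calls supplied; using expression-proxy filter "
            "(retain genes with >= %.0f%% of samples above the q=%.2f intensity quantile)",
            100 * (1 - threshold), proxy_quantile,
        )
        low = float(np.quantile(expr.to_numpy(), proxy_quantile))
        detected_frac = (expr.to_numpy() > low).mean(axis=1)
        keep = detected_frac >= (1 - threshold)
        return expr.loc[keep]
    if not expr.index.equals(calls.index) or not expr.columns.equals(calls.columns):
        raise ValueError("detection-call matrix is not aligned to the expression matrix")
    undetected = calls.isin(["A", "M"]).to_numpy().mean(axis=1)
    return expr.loc[undetected < threshold]


def center_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across samples (row-wise centering)."""
    if expr.shape[1] < 1:
        raise ValueError("need at least one sample")
    return expr.sub(expr.mean(axis=1), axis=0)


def l2_select(expr: pd.DataFrame, top_n: int = 7000) -> pd.DataFrame:
    """Keep the ``top_n`` genes with the largest L2 norm across samples.

    The L2 norm ``||g|| = sqrt(g_1^2 + ... + g_P^2)`` ranks genes by
    overall magnitude of (centered) expression.  Ties break
    lexicographically by gene ID for determinism; the result is ordered
    by descending norm.
    """
    n_genes = expr.shape[0]
    if top_n > n_genes:
        raise ValueError(f"top_n={top_n} exceeds the gene count {n_genes}")
    norms = pd.Series(np.linalg.norm(expr.to_numpy(), axis=1), index=expr.index)
    order = (
        pd.DataFrame({"norm": norms, "gene": norms.index.astype(str)})
        .sort_values(["norm", "gene"], ascending=[False, True])
        .index
    )
    return expr.loc[order[:top_n]]


def to_nonnegative(expr: pd.DataFrame, mode: str = "shift") -> pd.DataFrame:
    """Make a (typically centered) matrix valid NMF input.

    mode="shift" subtracts the global minimum, so the output minimum is 0
    and every pairwise difference is preserved; mode="clip" sets negative
    entries to 0, discarding below-baseline signal.
    """
    if mode == "shift":
        m = float(expr.to_numpy().min())
        return expr - m if m != 0.0 else expr.copy()
    if mode == "clip":
        return expr.clip(lower=0.0)
    raise ValueError(f"unknown nonnegativity mode {mode!r}; use 'shift' or 'clip'")
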